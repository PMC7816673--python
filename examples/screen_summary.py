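"""Reproduce the screening statistics from the packaged survey table.

The fixture lists 20 virus records found in 17 of 155 screened
Aspergillus strains; the tally recomputes every headline number.
"""

from fldskit import default_screened_counts, load_table1, render_table, tally_screen

records = load_table1()
summary = tally_screen(records, default_screened_counts())
_, text = render_table(summary, records)
print(text)
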