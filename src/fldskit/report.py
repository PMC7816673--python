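"""Screening summary statistics over strain-virus records.

Aggregates a table of virus records (one row per virus per host strain)
into the screen-level quantities: per-host-species positive frequencies,
AGE-detectable strain counts, segmentation breakdown, and OTU/novelty
counts.  A record is "segmented" when it has >= 2 segments; a record is
"complete" when its full genome sequence was determined (records whose
sequence could not be completed are excluded from the segmented-fraction
denominator, but a record whose termini were merely not fully resolved
still counts as a determined genome).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

REQUIRED_COLUMNS = [
    "strain", "species", "virus_name", "virus_abbrev", "n_segments",
    "genome_type", "method", "novel", "complete_sequence", "termini_complete",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (printed-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ScreenSummary:
    per_species: pd.DataFrame  # species, screened_n, positive_n, frequency_percent
    age_positive_strains: int
    screened_total: int
    age_positive_percent: float
    records_total: int
    strains_with_virus: int
    segmented_records: int
    segment_breakdown: dict[int, int]  # n_segments (>=2) -> record count
    complete_records: int
    segmented_percent_of_complete: float
    otu_count: int
    novel_otu_count: int


def load_table1() -> pd.DataFrame:
    """The packaged strain-virus screening fixture (20 records)."""
    source = importlib.resources.files("fldskit.data") / "table1.tsv"
    with importlib.resources.as_file(source) as path:
        df = pd.read_csv(path, sep="\t")
    for col in ("novel", "complete_sequence", "termini_complete"):
        if df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
    return df


def default_screened_counts() -> dict[str, int]:
    """Strains screened per host species in the survey (155 in total)."""
    return {
        "A. fumigatus": 79,
        "A. lentulus": 27,
        "A. pseudoviridinutans": 15,
        "A. udagawae": 19,
        "N. fischeri": 15,
    }


def tally_screen(
    records: pd.DataFrame, screened_counts: Mapping[str, int]
) -> ScreenSummary:
    """Compute all screening statistics from a strain-virus record table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table missing column(s) {missing}")
    present = set(records["species"].unique())
    uncovered = present - set(screened_counts)
    if uncovered:
        raise ValueError(
            f"species missing from screened_counts: {sorted(uncovered)}"
        )

    rows = []
    for species, screened_n in screened_counts.items():
        positive_n = records.loc[records["species"] == species, "strain"].nunique()
        freq = round_half_up(positive_n / screened_n * 100, 1) if screened_n else 0.0
        rows.append(
            {"species": species, "screened_n": screened_n,
             "positive_n": positive_n, "frequency_percent": freq}
        )
    per_species = pd.DataFrame(
        rows, columns=["species", "screened_n", "positive_n", "frequency_percent"]
    )

    screened_total = int(sum(screened_counts.values()))
    age_strains = records.loc[
        records["method"].str.contains("AGE"), "strain"
    ].nunique()
    age_pct = (
        round_half_up(age_strains / screened_total * 100, 1) if screened_total else 0.0
    )

    records_total = len(records)
    strains_with_virus = records["strain"].nunique()
    seg = records[records["n_segments"] >= 2]
    breakdown = seg["n_segments"].value_counts().sort_index().to_dict()
    breakdown = {int(k): int(v) for k, v in breakdown.items()}
    complete_records = int(records["complete_sequence"].sum())
    seg_pct = (
        round_half_up(len(seg) / complete_records * 100)
        if complete_records
        else 0.0
    )
    otu_count = records["virus_name"].nunique()
    novel_otus = records.loc[records["novel"], "virus_name"].nunique()

    return ScreenSummary(
        per_species=per_species,
        age_positive_strains=int(age_strains),
        screened_total=screened_total,
        age_positive_percent=age_pct,
        records_total=records_total,
        strains_with_virus=int(strains_with_virus),
        segmented_records=int(len(seg)),
        segment_breakdown=breakdown,
        complete_records=complete_records,
        segmented_percent_of_complete=seg_pct,
        otu_count=int(otu_count),
        novel_otu_count=int(novel_otus),
    )


def render_table(
    summary: ScreenSummary, records: pd.DataFrame
) -> tuple[pd.DataFrame, str]:
    """Deterministic record table plus a human-readable claim-by-claim
    report; the returned table round-trips through TSV."""
    table = records[REQUIRED_COLUMNS].copy()

    lines = ["Screening summary", "================="]
    for _, r in summary.per_species.iterrows():
        lines.append(
            f"{r['species']}: {r['positive_n']}/{r['screened_n']} strains "
            f"virus-positive ({r['frequency_percent']}%)"
        )
    lines += [
        f"AGE-positive strains: {summary.age_positive_strains}/"
        f"{summary.screened_total} ({summary.age_positive_percent}%)",
        f"Virus records: {summary.records_total} in "
        f"{summary.strains_with_virus} strains",
        f"Species groups (OTU proxy): {summary.otu_count} "
        f"({summary.novel_otu_count} novel)",
        f"Segmented records: {summary.segmented_records} "
        + "(" + ", ".join(
            f"{v} x {k}-segment" for k, v in sorted(summary.segment_breakdown.items())
        ) + ")",
        f"Complete records: {summary.complete_records}",
        f"Segmented fraction of complete records: "
        f"{summary.segmented_percent_of_complete:.0f}%",
        "",
        "Note: the segmented fraction is computed over records whose full",
        "genome sequence was determined; a record with unresolved termini",
        "but a determined sequence still counts as complete.",
    ]
    return table, "\n".join(lines)
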