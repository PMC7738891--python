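"""Readers and writers for the pipeline's tabular interchange formats.

Everything is plain TSV with a header row (GMT being the one standard
exception: tab-separated `pathway_id, description, gene, gene, ...`).
Counts matrices are pandas DataFrames indexed by ``feature_id`` with one
column per sample.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

SAMPLE_SHEET_COLS = ["sample_id", "donor", "condition"]
INTERACTION_COLS = ["source", "target", "type", "direction"]
CONDITIONS = ("control", "treated")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    validate_sample_sheet(sheet)
    return sheet


def validate_sample_sheet(sheet: pd.DataFrame) -> None:
    """Fail fast on malformed sample sheets (bad labels, broken pairing)."""
    missing = set(SAMPLE_SHEET_COLS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad = set(sheet["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(
            f"invalid condition labels {sorted(bad)}; expected {CONDITIONS}"
        )
    per = sheet.groupby(["donor", "condition"]).size()
    if (per != 1).any():
        raise ValueError("each donor must appear exactly once per condition")
    n_donors = sheet["donor"].nunique()
    if n_donors < 3:
        raise ValueError(f"need >=3 donors, got {n_donors}")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet[SAMPLE_SHEET_COLS].to_csv(path, sep="\t", index=False)


def read_interactions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_interactions(cat: pd.DataFrame, path: str | Path) -> None:
    cat.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for pid in sorted(sets):
            desc = (descriptions or {}).get(pid, "na")
            genes = "\t".join(sorted(sets[pid]))
            fh.write(f"{pid}\t{desc}\t{genes}\n")


def read_hierarchy(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_roots(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_triplexes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"mirna1": str, "mirna2": str, "gene": str},
    )


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, set):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
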