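"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are tab-separated.  The peptide report is long format with columns
``sample, group, fraction, peptide, protein, abundance, qvalue``; protein
matrices are proteins-as-rows with a leading ``protein`` column and a sidecar
``samples.tsv`` mapping sample to group; contrast results are
``protein, log2fc, pvalue``; gene sets use the GMT dialect and rankings the
two-column RNK dialect.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

PEPTIDE_COLUMNS = ["sample", "group", "fraction", "peptide", "protein", "abundance", "qvalue"]


def read_peptide_report(path: str | Path) -> pd.DataFrame:
    report = pd.read_csv(path, sep="\t")
    missing = set(PEPTIDE_COLUMNS) - set(report.columns)
    if missing:
        raise ValueError(f"peptide report missing columns: {sorted(missing)}")
    return report[PEPTIDE_COLUMNS]


def write_peptide_report(report: pd.DataFrame, path: str | Path) -> None:
    report[PEPTIDE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_protein_matrix(path: str | Path, samples_path: str | Path | None = None) -> tuple[pd.DataFrame, dict[str, str]]:
    """Protein x sample matrix plus the sample -> group map from the sidecar."""
    matrix = pd.read_csv(path, sep="\t").set_index("protein")
    groups: dict[str, str] = {}
    if samples_path is None:
        candidate = Path(path).with_name("samples.tsv")
        samples_path = candidate if candidate.exists() else None
    if samples_path is not None:
        sidecar = pd.read_csv(samples_path, sep="\t")
        groups = dict(zip(sidecar["sample"], sidecar["group"]))
    return matrix, groups


def write_protein_matrix(matrix: pd.DataFrame, groups: Mapping[str, str], path: str | Path) -> None:
    path = Path(path)
    matrix.rename_axis("protein").to_csv(path, sep="\t")
    pd.DataFrame({"sample": list(matrix.columns), "group": [groups[s] for s in matrix.columns]}).to_csv(
        path.with_name("samples.tsv"), sep="\t", index=False
    )


def read_contrast(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("protein")[["log2fc", "pvalue"]]


def write_contrast(result: pd.DataFrame, path: str | Path) -> None:
    result.rename_axis("protein").reset_index()[["protein", "log2fc", "pvalue"]].to_csv(
        path, sep="\t", index=False
    )


def read_modules(path: str | Path) -> pd.Series:
    table = pd.read_csv(path, sep="\t")
    return pd.Series(table["module"].values, index=table["protein"].values, name="module")


def write_modules(assignment: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame({"protein": list(assignment), "module": list(assignment.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in sets:
                raise ValueError(f"duplicate gene-set name: {name}")
            sets[name] = (desc, members)
    return sets


def write_gmt(sets: Mapping[str, tuple[str, list[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_rnk(path: str | Path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", header=None, names=["token", "score"], comment="#")
    return pd.Series(table["score"].values, index=table["token"].values, name="score")


def write_rnk(ranking: pd.Series, path: str | Path) -> None:
    ranking.sort_values(ascending=False).to_csv(path, sep="\t", header=False)
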