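"""Plain-text table dialects shared by the simulator and the pipeline.

Genotypes travel as TSV (marker, chr, cM, bp, one column per line with
A/B/H calls); phenotypes as tidy CSV (line, rep, DAS, trait, value);
fitted parameters and reports as CSV/JSON. The simulator writes the same
dialects the pipeline reads, so round trips are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .scan import GenotypeData

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "write_json",
]

_CODE_TO_DOSAGE = {"A": 0, "H": 1, "B": 2}
_DOSAGE_TO_CODE = np.array(["A", "H", "B"])


def write_genotypes(gdata: GenotypeData, path) -> None:
    codes = _DOSAGE_TO_CODE[gdata.genotypes]  # (n_lines, n_markers)
    tab = pd.concat(
        [gdata.markers[["marker", "chrom", "cM", "bp"]],
         pd.DataFrame(codes.T, columns=gdata.line_names)],
        axis=1,
    )
    tab.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeData:
    tab = pd.read_csv(path, sep="\t")
    fixed = ["marker", "chrom", "cM", "bp"]
    missing = [c for c in fixed if c not in tab.columns]
    if missing:
        raise ValueError(f"genotype table missing columns {missing}")
    lines = [c for c in tab.columns if c not in fixed]
    if not lines:
        raise ValueError("genotype table has no line columns")
    codes = tab[lines].to_numpy(dtype=str)
    bad = ~np.isin(codes, list(_CODE_TO_DOSAGE))
    if bad.any():
        raise ValueError(
            f"unknown allele codes {sorted(set(codes[bad]))!r}; expected A/B/H"
        )
    dosage = np.vectorize(_CODE_TO_DOSAGE.get)(codes).T.astype(np.int8)
    return GenotypeData(markers=tab[fixed].reset_index(drop=True),
                        line_names=lines, genotypes=dosage)


def write_phenotypes(series: pd.DataFrame, path) -> None:
    series[["line", "rep", "DAS", "trait", "value"]].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    tab = pd.read_csv(path)
    required = ["line", "rep", "DAS", "trait", "value"]
    missing = [c for c in required if c not in tab.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns {missing}")
    return tab[required]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
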