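"""Cross-docking bookkeeping over a benchmark of binary complexes.

A benchmark of C binary complexes contributes 2C proteins (receptor and
ligand of each complex, suffixed ``_r`` / ``_l``); complete cross-docking
enumerates every ordered (receptor, ligand) pair including self-pairs,
hence (2C)^2 docking runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .evaluation import GoldStandard


@dataclass
class Benchmark:
    """Protein inventory of a binary-complex benchmark."""

    complexes: list[str]                 # complex codes
    pairs: list[tuple[str, str]]         # (receptor_id, ligand_id) per complex

    @property
    def proteins(self) -> list[str]:
        out = []
        for r, l in self.pairs:
            out.extend((r, l))
        return out

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_complexes(self) -> int:
        return len(self.complexes)

    def gold_standard(self) -> GoldStandard:
        return GoldStandard(native_pairs={frozenset(p) for p in self.pairs},
                            universe=set(self.proteins))


def ordered_pairs(proteins: Sequence[str],
                  include_self: bool = True) -> list[tuple[str, str]]:
    """All ordered (receptor, ligand) pairs of a protein set."""
    return [(r, l) for r in proteins for l in proteins
            if include_self or r != l]


def n_ordered_pairs(n_proteins: int, include_self: bool = True) -> int:
    return n_proteins * n_proteins if include_self \
        else n_proteins * (n_proteins - 1)


def n_cross_pairs(n_receptors: int, n_ligands: int) -> int:
    """Receptor-set x ligand-set docking runs."""
    return n_receptors * n_ligands


def make_benchmark(complex_codes: Iterable[str]) -> Benchmark:
    """Benchmark from complex codes; each complex yields an ``_r`` and an
    ``_l`` protein."""
    codes = list(complex_codes)
    return Benchmark(codes, [(f"{c}_r", f"{c}_l") for c in codes])


def synthetic_benchmark(n_complexes: int) -> Benchmark:
    """Synthetic benchmark skeleton with ``n_complexes`` binary complexes."""
    return make_benchmark(f"C{k:03d}" for k in range(n_complexes))


def load_benchmark(path: str | Path) -> Benchmark:
    """Read a complex table: TSV with columns ``complex``, ``receptor``,
    ``ligand`` (or a single ``complex`` column, expanded to _r/_l ids)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if {"receptor", "ligand"} <= set(df.columns):
        return Benchmark(list(df["complex"]),
                         list(zip(df["receptor"], df["ligand"])))
    return make_benchmark(df["complex"])
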