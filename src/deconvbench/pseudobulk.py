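"""Pseudo-bulk mixture generation with known ground-truth proportions.

Each mixture draws a number of cell types k uniformly from ``k_range``,
k distinct types uniformly, and a composition uniformly from all grid
compositions of length k summing to one (via uniform cut points in the
integer-unit representation, so no sequential-draw bias).  Cells are
sampled without replacement within a mixture and their raw counts are
summed; reuse across mixtures is allowed.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd

from .io_qc import CellExpressionMatrix


class MixtureError(RuntimeError):
    pass


@dataclasses.dataclass
class CompositionRules:
    n_mixtures: int = 1000
    pool_size: int = 100
    k_range: tuple = (2, 5)
    grid_step: float = 0.05
    grid_min: float = 0.05
    seed: int = 0
    max_rejections: int = 1000

    def __post_init__(self) -> None:
        units = 1.0 / self.grid_step
        if abs(units - round(units)) > 1e-9:
            raise ValueError("grid_step must divide 1 exactly")
        min_units = self.grid_min / self.grid_step
        if abs(min_units - round(min_units)) > 1e-9:
            raise ValueError("grid_min must be a multiple of grid_step")
        if self.k_range[0] < 1 or self.k_range[1] < self.k_range[0]:
            raise ValueError("invalid k_range")
        if self.n_mixtures < 1 or self.pool_size < 1:
            raise ValueError("n_mixtures and pool_size must be positive")

    @property
    def units(self) -> int:
        return int(round(1.0 / self.grid_step))

    @property
    def min_units(self) -> int:
        return int(round(self.grid_min / self.grid_step))


def kidney_rules(**overrides) -> CompositionRules:
    """The kidney-style preset: 2-8 types, 0.01 grid on [0.01, 0.99]."""
    defaults = dict(k_range=(2, 8), grid_step=0.01, grid_min=0.01)
    defaults.update(overrides)
    return CompositionRules(**defaults)


@dataclasses.dataclass
class MixtureSet:
    T: np.ndarray  # genes x mixtures, summed raw counts
    P_E: np.ndarray  # cell types x mixtures, ground-truth proportions
    gene_ids: np.ndarray
    cell_type_ids: list
    mixture_ids: list
    provenance: list  # per mixture: array of selected cell ids
    rules: CompositionRules

    def validate(self) -> None:
        assert self.T.shape == (len(self.gene_ids), len(self.mixture_ids))
        assert self.P_E.shape == (len(self.cell_type_ids), len(self.mixture_ids))
        colsums = self.P_E.sum(axis=0)
        assert np.all(np.abs(colsums - 1.0) <= 1e-12)
        for ids in self.provenance:
            assert len(ids) == len(set(ids))

    @property
    def n_mixtures(self) -> int:
        return self.T.shape[1]

    def proportions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P_E, index=self.cell_type_ids, columns=self.mixture_ids)

    def to_tsv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.T, index=self.gene_ids, columns=self.mixture_ids).to_csv(
            outdir / "T.tsv", sep="\t"
        )
        self.proportions_frame().to_csv(outdir / "P_E.tsv", sep="\t")
        rows = [
            {"mixture": m, "cell_id": c}
            for m, ids in zip(self.mixture_ids, self.provenance)
            for c in ids
        ]
        pd.DataFrame(rows).to_csv(outdir / "provenance.tsv", sep="\t", index=False)


def enumerate_grid_compositions(
    k: int, grid_step: float = 0.05, grid_min: float = 0.05
) -> list:
    """All length-k tuples of grid proportions summing to 1.

    Compositions correspond to cut points of the unit total: U units into
    k parts, each at least the grid minimum.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    units = int(round(1.0 / grid_step))
    min_units = int(round(grid_min / grid_step))
    free = units - k * min_units
    if free < 0:
        return []
    n_comps = math.comb(free + k - 1, k - 1)
    if n_comps > 2_000_000:
        raise ValueError(
            f"{n_comps} compositions; enumeration is infeasible, sample instead"
        )
    out = []
    for cuts in itertools.combinations(range(1, free + k), k - 1):
        bounds = (0,) + cuts + (free + k,)
        parts = tuple(bounds[i + 1] - bounds[i] - 1 + min_units for i in range(k))
        out.append(tuple(p / units for p in parts))
    return out


def _sample_composition(rng: np.random.Generator, k: int, rules: CompositionRules) -> np.ndarray:
    """Uniform draw over grid compositions, in integer units."""
    units, min_units = rules.units, rules.min_units
    free = units - k * min_units
    if free < 0:
        raise MixtureError(
            f"no composition of {k} parts fits the grid (min {rules.grid_min})"
        )
    if k == 1:
        return np.array([units])
    cuts = np.sort(rng.choice(free + k - 1, size=k - 1, replace=False)) + 1
    bounds = np.concatenate([[0], cuts, [free + k]])
    return np.diff(bounds) - 1 + min_units


def _cells_per_type(parts_units: np.ndarray, rules: CompositionRules) -> np.ndarray:
    """Integer cell counts for a composition; largest-remainder fallback."""
    exact = parts_units * rules.pool_size / rules.units
    counts = np.floor(exact + 1e-9).astype(int)
    deficit = rules.pool_size - counts.sum()
    if deficit > 0:
        remainders = exact - counts
        # deterministic tie-break: larger remainder first, then lower index
        order = np.lexsort((np.arange(len(exact)), -remainders))
        counts[order[:deficit]] += 1
    return counts


def generate_mixtures(
    test: CellExpressionMatrix, rules: CompositionRules, seed: int | None = None
) -> MixtureSet:
    """Build a :class:`MixtureSet` from the test split under ``rules``."""
    rng = np.random.default_rng(rules.seed if seed is None else seed)
    types = test.cell_types()
    k_lo, k_hi = rules.k_range
    if k_hi > len(types):
        raise MixtureError(
            f"k_range max {k_hi} exceeds the {len(types)} available cell types"
        )
    type_indices = {t: np.flatnonzero(test.cell_type == t) for t in types}
    for t in types:
        if len(type_indices[t]) == 0:
            raise MixtureError(f"cell type {t!r} has no cells in the test split")

    n_genes = test.n_genes
    T = np.zeros((n_genes, rules.n_mixtures))
    P_E = np.zeros((len(types), rules.n_mixtures))
    provenance = []
    type_pos = {t: i for i, t in enumerate(types)}

    for m in range(rules.n_mixtures):
        k = int(rng.integers(k_lo, k_hi + 1))
        chosen = list(rng.choice(len(types), size=k, replace=False))
        chosen_types = [types[i] for i in chosen]
        for attempt in range(rules.max_rejections):
            parts = _sample_composition(rng, k, rules)
            n_cells = _cells_per_type(parts, rules)
            if all(
                n <= len(type_indices[t]) for n, t in zip(n_cells, chosen_types)
            ):
                break
        else:
            worst = max(
                zip(n_cells, chosen_types), key=lambda x: x[0] - len(type_indices[x[1]])
            )[1]
            raise MixtureError(
                f"no feasible composition after {rules.max_rejections} draws; "
                f"cell type {worst!r} has too few cells for pool size "
                f"{rules.pool_size}"
            )
        picked = []
        for n, t in zip(n_cells, chosen_types):
            picked.append(rng.choice(type_indices[t], size=n, replace=False))
        picked = np.concatenate(picked)
        T[:, m] = test.counts[:, picked].sum(axis=1)
        for part, t in zip(parts, chosen_types):
            P_E[type_pos[t], m] = part / rules.units
        provenance.append(list(test.cell_ids[picked]))

    mix = MixtureSet(
        T=T,
        P_E=P_E,
        gene_ids=test.gene_ids,
        cell_type_ids=types,
        mixture_ids=[f"mix{m:04d}" for m in range(rules.n_mixtures)],
        provenance=provenance,
        rules=rules,
    )
    mix.validate()
    return mix
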