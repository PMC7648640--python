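"""Synthetic scRNA-seq generator with known markers and type correlations.

Counts are negative-binomially distributed (variance = mu + alpha * mu^2)
around type-specific mean profiles.  Each profile is a blend of a shared
pool profile and an independent one, so expected between-type correlation
is tunable: a ``pool_weight`` of 0 makes a type uncorrelated with every
other, and explicit ``correlation_pairs`` blend two types directly.
Marker genes are disjoint blocks, over-expressed by a configurable fold
change in their own type; the planted map travels with the dataset as
``true_markers``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_qc import CellExpressionMatrix


@dataclasses.dataclass
class CellTypeSpec:
    name: str
    n_cells: int
    mean_library_size: float = 2000.0
    #: weight of the shared pool profile; None -> SyntheticSpec.baseline_similarity
    pool_weight: float | None = None


@dataclasses.dataclass
class SyntheticSpec:
    n_genes: int
    cell_types: list
    n_donors: int = 2
    marker_frac: float = 0.05
    marker_fold_change: float = 4.0
    #: scales the common cross-type baseline of marker blocks; lowering it
    #: keeps planted fold changes exact while letting non-marker genes
    #: dominate between-type profile correlations
    marker_baseline_scale: float = 1.0
    nb_dispersion: float = 0.2
    donor_effect_sd: float = 0.1
    library_size_sd: float = 0.25
    baseline_similarity: float = 0.4
    correlation_pairs: list = dataclasses.field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or not self.cell_types:
            raise ValueError("need at least one gene and one cell type")
        if not (0 <= self.marker_frac <= 1):
            raise ValueError("marker_frac must be in [0, 1]")
        if self.marker_frac * len(self.cell_types) > 1:
            raise ValueError(
                "infeasible spec: marker_frac x n_types > 1, marker blocks "
                "cannot be disjoint"
            )
        if self.marker_fold_change < 1:
            raise ValueError("marker_fold_change must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        names = [ct.name for ct in self.cell_types]
        if len(set(names)) != len(names):
            raise ValueError("cell type names must be unique")
        for a, b, s in self.correlation_pairs:
            if a not in names or b not in names:
                raise ValueError(f"correlation pair ({a}, {b}) names unknown type")
            if not (0 <= s <= 1):
                raise ValueError("similarity must lie in [0, 1]")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + alpha mu^2 (Poisson at alpha=0)."""
    mu = np.clip(mu, 1e-12, None)
    if alpha == 0:
        return rng.poisson(mu).astype(np.float64)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mu)
    return rng.poisson(lam).astype(np.float64)


def _draw_profiles(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[dict, dict]:
    """Type mean profiles and the planted marker map.

    Marker blocks are reset to the shared baseline in *every* type
    before the own-type boost, so the planted fold change is realized
    against the second-highest-expressing type, not against an arbitrary
    independent baseline.
    """
    n_genes = spec.n_genes
    names = [ct.name for ct in spec.cell_types]
    shared = rng.lognormal(0.0, 1.0, n_genes)
    profiles: dict[str, np.ndarray] = {}
    for ct in spec.cell_types:
        w = spec.baseline_similarity if ct.pool_weight is None else ct.pool_weight
        indep = rng.lognormal(0.0, 1.0, n_genes)
        profiles[ct.name] = w * shared + (1.0 - w) * indep
    for a, b, s in spec.correlation_pairs:
        profiles[b] = s * profiles[a] + (1.0 - s) * profiles[b]

    n_mark = int(round(spec.marker_frac * n_genes))
    pool = rng.permutation(n_genes)
    marker_blocks: dict[str, np.ndarray] = {}
    beta = spec.marker_baseline_scale
    for i, name in enumerate(names):
        block = pool[i * n_mark : (i + 1) * n_mark]
        marker_blocks[name] = np.sort(block)
        for other in names:
            profiles[other][block] = beta * shared[block]
        profiles[name][block] = beta * shared[block] * spec.marker_fold_change
    return profiles, marker_blocks


def generate_dataset(spec: SyntheticSpec) -> CellExpressionMatrix:
    """Draw a labelled count matrix from ``spec``; reproducible under seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_genes = spec.n_genes
    names = [ct.name for ct in spec.cell_types]
    profiles, marker_blocks = _draw_profiles(spec, rng)
    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)
    true_markers = {
        name: [gene_ids[j] for j in block] for name, block in marker_blocks.items()
    }

    donor_ids = [f"D{i}" for i in range(spec.n_donors)]
    donor_factors = rng.lognormal(0.0, spec.donor_effect_sd, (spec.n_donors, n_genes))

    blocks = []
    cell_type_labels: list[str] = []
    donor_labels: list[str] = []
    for ct in spec.cell_types:
        donors = rng.integers(0, spec.n_donors, ct.n_cells)
        libs = rng.lognormal(np.log(ct.mean_library_size), spec.library_size_sd, ct.n_cells)
        base = profiles[ct.name]
        mu = base[:, None] * donor_factors[donors].T  # genes x cells
        mu = mu / mu.sum(axis=0, keepdims=True) * libs[None, :]
        blocks.append(_nb_draw(rng, mu, spec.nb_dispersion))
        cell_type_labels.extend([ct.name] * ct.n_cells)
        donor_labels.extend([donor_ids[d] for d in donors])

    counts = np.concatenate(blocks, axis=1)
    cell_ids = np.array([f"C{i:05d}" for i in range(counts.shape[1])], dtype=object)
    return CellExpressionMatrix(
        counts,
        gene_ids,
        cell_ids,
        np.asarray(cell_type_labels, dtype=object),
        np.asarray(donor_labels, dtype=object),
        true_markers=true_markers,
    )


def expected_profiles(spec: SyntheticSpec) -> tuple[np.ndarray, list]:
    """Generating mean profiles (genes x types), for oracle checks in tests.

    Re-derives the same profile draws as :func:`generate_dataset` by
    replaying the generator's random stream.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = [ct.name for ct in spec.cell_types]
    profiles, _ = _draw_profiles(spec, rng)
    return np.column_stack([profiles[n] for n in names]), names


# ---------------------------------------------------------------------------
# Benchmark presets
# ---------------------------------------------------------------------------

PRESETS = ("pancreas_like", "pbmc_like", "kidney_like")


def preset_spec(preset: str, seed: int = 0) -> SyntheticSpec:
    """The SyntheticSpec behind each benchmark preset."""
    if preset == "pancreas_like":
        cts = [
            CellTypeSpec("alpha", 200),
            CellTypeSpec("beta", 200),
            CellTypeSpec("gamma", 200),
            CellTypeSpec("delta", 200),
            CellTypeSpec("acinar", 200),
        ]
        return SyntheticSpec(
            n_genes=1500,
            cell_types=cts,
            n_donors=3,
            marker_frac=0.04,
            marker_fold_change=4.0,
            nb_dispersion=0.2,
            seed=seed,
        )
    if preset == "pbmc_like":
        cts = [
            CellTypeSpec("T", 200),
            CellTypeSpec("NK", 200),
            CellTypeSpec("B", 200),
            CellTypeSpec("CD14_mono", 200),
            CellTypeSpec("dendritic", 200),
            # near-uncorrelated with every other type
            CellTypeSpec("CD34", 200, pool_weight=0.0),
            # too small: dropped by QC
            CellTypeSpec("rare", 30),
        ]
        return SyntheticSpec(
            n_genes=1500,
            cell_types=cts,
            n_donors=2,
            marker_frac=0.04,
            marker_fold_change=4.0,
            marker_baseline_scale=0.4,
            nb_dispersion=0.2,
            correlation_pairs=[("T", "NK", 0.85)],
            seed=seed,
        )
    if preset == "kidney_like":
        cts = [CellTypeSpec(f"kidney_t{i}", 160) for i in range(8)]
        return SyntheticSpec(
            n_genes=1600,
            cell_types=cts,
            n_donors=2,
            marker_frac=0.03,
            marker_fold_change=4.0,
            nb_dispersion=0.2,
            seed=seed,
        )
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


def make_benchmark_fixture(preset: str, seed: int = 0) -> CellExpressionMatrix:
    """A small dataset that passes QC with non-trivial removals.

    On top of the preset draw, a block of all-zero genes is appended and
    a few cells are inflated to extreme library sizes, so the QC stage
    has real work to do.
    """
    X = generate_dataset(preset_spec(preset, seed))
    rng = np.random.default_rng([seed, 0xBEEF])

    n_zero = 25
    zero_genes = np.zeros((n_zero, X.n_cells))
    counts = np.vstack([X.counts, zero_genes])
    gene_ids = np.concatenate(
        [X.gene_ids, np.array([f"ZERO{i:03d}" for i in range(n_zero)], dtype=object)]
    )

    outliers = rng.choice(X.n_cells, size=3, replace=False)
    counts[:, outliers] *= 30

    return CellExpressionMatrix(
        counts,
        gene_ids,
        X.cell_ids,
        X.cell_type,
        X.donor,
        true_markers=X.true_markers,
    )
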