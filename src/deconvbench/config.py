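"""Pipeline configuration: defaults, serialization, derived stage seeds."""

from __future__ import annotations

import dataclasses
import hashlib

import yaml


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed deterministically from the master seed."""
    digest = hashlib.sha256(f"{stage}:{master_seed}".encode()).hexdigest()
    return int(digest[:8], 16)


@dataclasses.dataclass
class PipelineConfig:
    """Everything a benchmark run needs; defaults are the benchmark's.

    Data comes either from ``preset`` (synthetic) or ``data_path``
    (MTX layout / delimited matrix on disk).
    """

    preset: str | None = "pancreas_like"
    data_path: str | None = None
    seed: int = 0

    # QC
    qc_n_mads: float = 3.0
    qc_min_frac_cells: float = 0.05
    qc_min_cells_per_type: int = 50

    # splitting
    split_mode: str = "by_cell"

    # markers
    fc_threshold: float = 2.0
    marker_alpha: float = 0.05
    marker_min_expr_frac: float = 0.30
    marker_strategies: tuple = ("all",)

    # mixtures
    n_mixtures: int = 1000
    pool_size: int = 100
    k_range: tuple = (2, 5)
    grid_step: float = 0.05
    grid_min: float = 0.05

    # grid
    transforms: tuple = ("linear",)
    scaling_t: tuple = ("column",)
    scaling_c: tuple = ("column",)
    methods: tuple = ("nnls",)
    solver_kwargs: dict = dataclasses.field(default_factory=dict)

    output_dir: str | None = None

    def load_data(self):
        from .io_qc import read_counts
        from .synthetic import make_benchmark_fixture

        if self.data_path is not None:
            return read_counts(self.data_path)
        if self.preset is None:
            raise ValueError("config names neither a preset nor a data path")
        return make_benchmark_fixture(self.preset, seed=stage_seed(self.seed, "data"))

    def composition_rules(self):
        from .pseudobulk import CompositionRules

        return CompositionRules(
            n_mixtures=self.n_mixtures,
            pool_size=self.pool_size,
            k_range=tuple(self.k_range),
            grid_step=self.grid_step,
            grid_min=self.grid_min,
            seed=stage_seed(self.seed, "mixtures"),
        )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        d["marker_strategies"] = list(self.marker_strategies)
        d["transforms"] = list(self.transforms)
        d["scaling_t"] = list(self.scaling_t)
        d["scaling_c"] = list(self.scaling_c)
        d["methods"] = list(self.methods)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("k_range", "marker_strategies", "transforms", "scaling_t", "scaling_c", "methods"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
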