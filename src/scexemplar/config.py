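"""Run configuration shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass
class RunConfig:
    """Flat bag of tunable parameters with the pipeline defaults.

    Fractions are in (0, 1]; ``edge_quantile`` is the quantile *position* used
    for the empirical RTKE edge threshold (0.994 keeps the upper 0.006 tail).
    """

    top_k_fraction: float = 0.10
    edge_quantile: float = 0.994
    signature_gene_fraction: float = 0.20
    detection_threshold: float = 0.01
    min_cells_per_cluster: int = 50
    hdbscan_min_cluster_size: int = 20
    mixture_count: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("top_k_fraction", "edge_quantile", "signature_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")
        if not 0.0 <= self.detection_threshold < 1.0:
            raise ValueError(
                f"detection_threshold must be in [0, 1), got {self.detection_threshold!r}"
            )
        for name in ("min_cells_per_cluster", "hdbscan_min_cluster_size", "mixture_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat ``key = value`` (or ``key: value``) text file."""
        kwargs: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"float": float, "int": int}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.replace(":", "=", 1).partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise KeyError(f"unknown config key {key!r} in {path}")
            kwargs[key] = casts[types[key]](value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    def updated(self, **overrides) -> "RunConfig":
        """Copy with overrides (CLI flags beat config-file values)."""
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**current)
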