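"""Run configuration: one flat key/value structure mirrored 1:1 by CLI flags.

Defaults follow the method's standard protocol: 1,500 swap iterations per search,
1,000 consensus cycles, a 10% background fraction for the PC1 threshold, at
most 20 candidate biclusters, and a 0.05 significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass
class PipelineConfig:
    seed_size: int = 10
    iterations: int = 1500
    cycles: int = 1000
    background_fraction: float = 0.10
    max_k: int = 20
    rng_seed: int = 0
    correlation: str = "pearson"
    min_expression: float = 1.0
    screen_rho: float = 0.9
    screen_q: float = 0.6
    gsea_permutations: int = 1000
    alpha_level: float = 0.05

    def __post_init__(self) -> None:
        if self.seed_size < 3:
            raise ValueError("seed_size must be >= 3 (correlation needs >= 3 samples)")
        if self.iterations < 0 or self.cycles < 1:
            raise ValueError("iterations must be >= 0 and cycles >= 1")
        if not 0 < self.background_fraction < 1:
            raise ValueError("background_fraction must lie in (0, 1)")
        if self.max_k < 2:
            raise ValueError("max_k must be >= 2")
        if self.correlation != "pearson":
            raise ValueError("only pearson correlation is supported")
        if self.min_expression < 0:
            raise ValueError("min_expression must be >= 0")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must lie in (0, 1)")
        if self.gsea_permutations < 1:
            raise ValueError("gsea_permutations must be positive")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load a flat ``key = value`` text file; keyword overrides win."""
        values: dict = {}
        casts = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, raw = (part.strip() for part in line.split("=", 1))
                if key not in casts:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                default = getattr(cls, key, None)
                if isinstance(default, bool):
                    values[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    values[key] = int(raw)
                elif isinstance(default, float):
                    values[key] = float(raw)
                else:
                    values[key] = raw
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)
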