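"""Pipeline configuration: presets and YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import presets
from .simulate import TrialMeans, VarianceComponents


@dataclass
class TrialConfig:
    name: str
    n_cultivars: int
    n_blocks: int = 5
    n_rows: int = 8
    available_per_block: int | None = None  # None -> all cultivars available
    dup_count: int = 0
    plates_per_day: int = 4
    mean: float = 0.0
    terms: dict[str, float] = field(default_factory=dict)
    genetic_var: float = 1.0
    residual_var: float = 1.0


@dataclass
class PipelineConfig:
    trials: list[TrialConfig]
    n_shared: int  # cultivars common to all trials
    genetic_correlation: float = 0.0
    models: list[str] = field(default_factory=lambda: ["A", "B", "C"])
    k: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.models:
            if m not in ("A", "B", "C"):
                raise ValueError(f"unknown model {m!r}")
        if len({t.name for t in self.trials}) != len(self.trials):
            raise ValueError("trial names must be unique")

    def variance_components(self) -> VarianceComponents:
        return VarianceComponents(
            terms={t.name: dict(t.terms) for t in self.trials},
            genetic={t.name: t.genetic_var for t in self.trials},
            residual={t.name: t.residual_var for t in self.trials},
            genetic_correlation=self.genetic_correlation,
        )

    def trial_means(self) -> TrialMeans:
        return TrialMeans(means={t.name: t.mean for t in self.trials})

    def cultivar_lists(self) -> dict[str, list[str]]:
        """Synthetic id lists with ``n_shared`` cultivars common to all trials."""
        shared = [f"CV{i:04d}" for i in range(1, self.n_shared + 1)]
        out = {}
        for ti, t in enumerate(self.trials):
            extra = t.n_cultivars - self.n_shared
            if extra < 0:
                raise ValueError(f"trial {t.name}: n_shared exceeds n_cultivars")
            own = [f"CV{chr(65 + ti)}{i:04d}" for i in range(1, extra + 1)]
            out[t.name] = shared + own
        return out


def default_config(seed: int = 0) -> PipelineConfig:
    """Full-scale two-trial preset mirroring the original campaign layout."""
    return PipelineConfig(
        trials=[
            TrialConfig(
                name=presets.TRIAL_2010,
                n_cultivars=presets.LAYOUT_2010.n_cultivars,
                n_blocks=presets.LAYOUT_2010.n_blocks,
                n_rows=presets.LAYOUT_2010.n_rows,
                available_per_block=presets.LAYOUT_2010.available_per_block,
                dup_count=presets.LAYOUT_2010.dup_count,
                plates_per_day=presets.LAYOUT_2010.plates_per_day,
                mean=presets.TRIAL_MEANS[presets.TRIAL_2010],
                terms=dict(presets.VC_TERMS_2010),
                genetic_var=presets.GENETIC_VAR[presets.TRIAL_2010],
                residual_var=presets.RESIDUAL_VAR[presets.TRIAL_2010],
            ),
            TrialConfig(
                name=presets.TRIAL_2011,
                n_cultivars=presets.LAYOUT_2011.n_cultivars,
                n_blocks=presets.LAYOUT_2011.n_blocks,
                n_rows=presets.LAYOUT_2011.n_rows,
                available_per_block=presets.LAYOUT_2011.available_per_block,
                dup_count=presets.LAYOUT_2011.dup_count,
                plates_per_day=presets.LAYOUT_2011.plates_per_day,
                mean=presets.TRIAL_MEANS[presets.TRIAL_2011],
                terms=dict(presets.VC_TERMS_2011),
                genetic_var=presets.GENETIC_VAR[presets.TRIAL_2011],
                residual_var=presets.RESIDUAL_VAR[presets.TRIAL_2011],
            ),
        ],
        n_shared=presets.N_SHARED_CULTIVARS,
        genetic_correlation=presets.GENETIC_CORRELATION,
        seed=seed,
    )


def reduced_config(
    n_cultivars: int = 100, n_blocks: int = 3, dup_count: int = 4, seed: int = 0
) -> PipelineConfig:
    """Scaled-down preset (same variance structure) for tests and smoke runs."""
    cfg = default_config(seed=seed)
    for t in cfg.trials:
        t.n_cultivars = n_cultivars
        t.n_blocks = n_blocks
        t.available_per_block = None
        t.dup_count = dup_count
    cfg.n_shared = n_cultivars
    cfg.k = min(cfg.k, max(1, n_cultivars // 3))
    return cfg


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    trials = [TrialConfig(**t) for t in raw.pop("trials")]
    return PipelineConfig(trials=trials, **raw)


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False), encoding="utf-8")
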