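"""Analysis configuration: the single source of truth for every protocol
constant consumed by the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Protocol constants for one end-to-end analysis.

    Defaults follow the standard preictal directed-connectivity protocol:
    3-45 Hz band with a 60 Hz notch, 500 Hz target rate, 28-s epochs cut
    into 4-s segments, SBC order selection up to p=20, 100 phase-randomized
    surrogates per segment at significance level 0.05, and median pooling
    of per-segment channel scores.
    """

    band: tuple[float, float] = (3.0, 45.0)
    notch: float = 60.0
    target_fs: float = 500.0
    epoch_s: float = 28.0
    window_s: float = 4.0
    order_criterion: str = "sbc"
    p_min: int = 1
    p_max: int = 20
    n_surrogates: int = 100
    alpha: float = 0.05
    methods: tuple[str, ...] = ("pdc", "dtf")
    measures: tuple[str, ...] = ("inflow", "outflow")
    pooling: str = "median"
    threshold: bool = True
    freq_step: float = 0.5
    min_fs: float = 500.0
    min_preictal_s: float = 30.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.band = (float(self.band[0]), float(self.band[1]))
        self.methods = tuple(self.methods)
        self.measures = tuple(self.measures)
        self.validate()

    def validate(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError(f"invalid band {self.band}")
        if high >= self.target_fs / 2:
            raise ValueError(
                f"band edge {high} Hz >= Nyquist of target_fs "
                f"{self.target_fs} Hz")
        k = self.epoch_s / self.window_s
        if abs(k - round(k)) > 1e-9 or k < 1:
            raise ValueError(
                f"epoch_s={self.epoch_s} must be a positive multiple of "
                f"window_s={self.window_s}")
        if self.order_criterion not in ("sbc", "aic"):
            raise ValueError(f"unknown criterion {self.order_criterion!r}")
        if not 1 <= self.p_min <= self.p_max:
            raise ValueError("need 1 <= p_min <= p_max")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_surrogates < 0:
            raise ValueError("n_surrogates must be >= 0")
        bad = set(self.methods) - {"pdc", "dtf"}
        if bad or not self.methods:
            raise ValueError(f"unknown methods {bad}")
        bad = set(self.measures) - {"inflow", "outflow"}
        if bad or not self.measures:
            raise ValueError(f"unknown measures {bad}")
        if self.pooling not in ("median", "mean"):
            raise ValueError(f"unknown pooling {self.pooling!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        d["methods"] = list(self.methods)
        d["measures"] = list(self.measures)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
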