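"""Run configuration: one serializable object covering every pipeline stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of a full synthetic-cohort pipeline run.

    Desk-scale defaults (V=2000, T=400, n=40) keep an end-to-end run light;
    the full-scale geometry (V=20484, T=1110, TR=0.555 s) is available by
    config. All randomness derives from ``seed`` via spawned generators, so
    identical configs reproduce identical outputs bit for bit.
    """

    outdir: str = "salnet_run"
    seed: int = 0

    # geometry / acquisition
    V: int = 2000
    K: int = 17
    T: int = 400
    TR: float = 0.555
    n_subjects: int = 40
    sessions_per_subject: int = 2
    salience_index: int | None = None

    # synthetic signal and nuisance
    signal_amplitude: float = 1.0
    in_between_sd: float = 0.5
    out_between_sd: float = 0.05
    drift: float = 0.5
    motion: float = 0.3
    spike_rate: float = 0.005
    spike_amplitude: float = 8.0
    noise_sd: float = 1.0

    # preprocessing
    cutoff_hz: float = 0.01
    n_dct: int | None = None  # None: derive from cutoff
    practical_cutoff_pct: float = 5.0
    dvars_alpha: float = 0.05
    low_variance_threshold: float = 1e-10

    # prior and mapping
    prior_seed: int | None = None  # None: derived from seed
    alpha: float = 0.01
    correction: str = "bonferroni"

    # phenotypes / battery
    phenotype_noise_sd: float | None = None
    missing_t1_fraction: float = 17 / 220
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = sorted(set(raw) - set(known))
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**known)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
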