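"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: |gamma(15N) / gamma(1H)|, used to derive the 15N Larmor frequency from
#: the spectrometer proton frequency.
DEFAULT_GAMMA_RATIO = 0.10136767

CSP_MODES = ("mean", "two_sd", "mean_plus_two_sd")
TAUC_ESTIMATORS = ("threehalves", "classical")


@dataclass
class RunConfig:
    spectrometer_proton_mhz: float = 600.0
    gamma_ratio: float = DEFAULT_GAMMA_RATIO
    csp_threshold_mode: str = "mean_plus_two_sd"
    rc_table_id: str = "wishart1995"
    tauc_estimator: str = "threehalves"
    match_tol_ppm: float = 0.15
    scs_threshold_ppm: float = 1.0
    seed: int = 0
    strict: bool = False

    def __post_init__(self) -> None:
        if self.spectrometer_proton_mhz <= 0:
            raise ValueError("proton frequency must be positive")
        if not (0.09 < self.gamma_ratio < 0.11):
            raise ValueError(
                f"gamma_ratio {self.gamma_ratio} outside the plausible "
                "15N/1H range (0.09, 0.11)"
            )
        if self.csp_threshold_mode not in CSP_MODES:
            raise ValueError(f"csp_threshold_mode must be one of {CSP_MODES}")
        if self.tauc_estimator not in TAUC_ESTIMATORS:
            raise ValueError(f"tauc_estimator must be one of {TAUC_ESTIMATORS}")

    @property
    def nu_n_hz(self) -> float:
        """15N Larmor frequency in Hz."""
        return self.gamma_ratio * self.spectrometer_proton_mhz * 1e6

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML or JSON RunConfig; missing path yields defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    text = path.read_text()
    data = (
        json.loads(text)
        if path.suffix.lower() == ".json"
        else yaml.safe_load(text)
    ) or {}
    return RunConfig(**data)
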