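"""Run configuration: probe geometry, fit windows, bounds, noise scales.

Defaults encode the instrument as operated: B-NIRS source-detector distance
30 mm, DCS distance 20 mm, fit windows 815–845 nm (water), 680–800 nm (Hb),
680–845 nm (HbO₂/scattering), 770–900 nm (differential tracking).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .chromophores import INSTRUMENT_MIN_NM, INSTRUMENT_MAX_NM
from .errors import ConfigError

logger = logging.getLogger("oxflow")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

SCHEMA_VERSION = 1

#: Initial values and (lower, upper) bounds of the five baseline fit
#: parameters {WF, Hb_b [µM], HbO2_b [µM], A [mm⁻¹], alpha}.
DEFAULT_INITIALS = {"WF": 0.8, "Hb_b": 10.0, "HbO2_b": 40.0, "A": 1.0, "alpha": 2.7}
DEFAULT_BOUNDS = {
    "WF": (0.6, 0.95),
    "Hb_b": (0.0, 60.0),
    "HbO2_b": (0.0, 80.0),
    "A": (1e-6, 1.3),  # strictly positive: µs′ = 0 is not a valid medium
    "alpha": (0.6, 4.0),
}
PARAM_ORDER = ("WF", "Hb_b", "HbO2_b", "A", "alpha")


@dataclass
class RunConfig:
    """Validated configuration for the full pipeline."""

    rho_bnirs_mm: float = 30.0
    rho_dcs_mm: float = 20.0
    window_water: tuple[float, float] = (815.0, 845.0)
    window_hb: tuple[float, float] = (680.0, 800.0)
    window_first_deriv: tuple[float, float] = (680.0, 845.0)
    window_ucln: tuple[float, float] = (770.0, 900.0)
    initials: dict = field(default_factory=lambda: dict(DEFAULT_INITIALS))
    bounds: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_BOUNDS.items()})
    #: Expected photon counts in the measured spectrum at its brightest
    #: channel (sets the Poisson noise level of simulated spectra).
    photon_count_scale: float = 3.5e3
    #: Nominal DCS count rate proxy controlling correlator noise magnitude.
    dcs_noise_scale: float = 0.07
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("rho_bnirs_mm", "rho_dcs_mm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("window_water", "window_hb", "window_first_deriv", "window_ucln"):
            lo, hi = getattr(self, name)
            if not (INSTRUMENT_MIN_NM <= lo < hi <= INSTRUMENT_MAX_NM):
                raise ConfigError(
                    f"{name} [{lo}, {hi}] nm outside instrument range "
                    f"[{INSTRUMENT_MIN_NM}, {INSTRUMENT_MAX_NM}] nm"
                )
        missing = set(PARAM_ORDER) - set(self.initials)
        if missing:
            raise ConfigError(f"initials missing parameters: {sorted(missing)}")
        missing = set(PARAM_ORDER) - set(self.bounds)
        if missing:
            raise ConfigError(f"bounds missing parameters: {sorted(missing)}")
        for k in PARAM_ORDER:
            lo, hi = self.bounds[k]
            if not (lo < hi):
                raise ConfigError(f"bounds for {k} must satisfy lower < upper")
            if not (lo <= self.initials[k] <= hi):
                raise ConfigError(f"initial value for {k} outside its bounds")
        if self.photon_count_scale <= 0 or self.dcs_noise_scale < 0:
            raise ConfigError("noise scales must be positive")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    def config_hash(self) -> str:
        """Short provenance hash embedded in result files."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.pop("schema_version", None)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        for key in ("window_water", "window_hb", "window_first_deriv", "window_ucln"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "bounds" in raw:
            raw["bounds"] = {k: tuple(v) for k, v in raw["bounds"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), default_flow_style=None))
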