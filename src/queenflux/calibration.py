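"""Sensor-ratio to ATP-concentration calibration.

The excitation ratio of the biosensor increases monotonically with ATP.  The
exact ratio->mM curve depends on the instrument and is supplied by the user;
two parameterizations are shipped:

* ``linear``: atp = slope * ratio + intercept.  The default (slope 4, intercept
  0) maps a baseline ratio of 1.0 to the ~4 mM resting ATP level of budding
  yeast, matching the proportional regime the sensor is used in.
* ``hill``: the saturable binding curve
  ratio(atp) = r_min + (r_max - r_min) * atp^n / (K^n + atp^n),
  inverted analytically to map ratio -> mM.  At ratio midway between r_min and
  r_max, atp equals the apparent dissociation constant ``k_app``.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

__all__ = ["CalibrationCurve"]


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone map between sensor ratio and ATP concentration (mM)."""

    model: str = "linear"  # "linear" | "hill"
    slope: float = 4.0
    intercept: float = 0.0
    r_min: float = 0.0
    r_max: float = 2.0
    k_app: float = 4.0  # mM
    hill_n: float = 1.0
    ratio_range: tuple[float, float] = (1e-6, 10.0)

    def __post_init__(self) -> None:
        if self.model not in ("linear", "hill"):
            raise ValueError(f"unknown calibration model {self.model!r}")
        if self.model == "linear" and self.slope <= 0:
            raise ValueError("linear calibration requires slope > 0")
        if self.model == "hill":
            if not (self.r_max > self.r_min):
                raise ValueError("hill calibration requires r_max > r_min")
            if self.k_app <= 0 or self.hill_n <= 0:
                raise ValueError("hill calibration requires k_app > 0 and hill_n > 0")
        lo, hi = self.ratio_range
        if not hi > lo:
            raise ValueError("ratio_range must be increasing")
        # numeric monotonicity check on a grid of the valid range
        grid = np.linspace(*self._clipped_range(), 257)
        atp = self.atp_from_ratio(grid, clip=False)
        if np.any(np.diff(atp) <= 0):
            raise ValueError("calibration must be strictly increasing over its valid range")

    def _clipped_range(self) -> tuple[float, float]:
        lo, hi = self.ratio_range
        if self.model == "hill":
            eps = 1e-9 * (self.r_max - self.r_min)
            lo = max(lo, self.r_min + eps)
            hi = min(hi, self.r_max - eps)
        return lo, hi

    def atp_from_ratio(self, ratio, clip: bool = True):
        """Forward map ratio -> ATP (mM); out-of-range input clipped when asked."""
        r = np.asarray(ratio, dtype=float)
        if clip:
            r = np.clip(r, *self._clipped_range())
        if self.model == "linear":
            out = self.slope * r + self.intercept
        else:
            frac = (r - self.r_min) / (self.r_max - r)
            out = self.k_app * np.power(frac, 1.0 / self.hill_n)
        return out if out.ndim else float(out)

    def ratio_from_atp(self, atp):
        """Inverse map ATP (mM) -> ratio."""
        a = np.asarray(atp, dtype=float)
        if self.model == "linear":
            out = (a - self.intercept) / self.slope
        else:
            an = np.power(a, self.hill_n)
            out = self.r_min + (self.r_max - self.r_min) * an / (self.k_app**self.hill_n + an)
        return out if out.ndim else float(out)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "slope": self.slope,
                "intercept": self.intercept,
                "r_min": self.r_min,
                "r_max": self.r_max,
                "k_app": self.k_app,
                "hill_n": self.hill_n,
                "ratio_range": list(self.ratio_range),
            },
            sort_keys=True,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        d = dict(d)
        if "ratio_range" in d:
            d["ratio_range"] = tuple(d["ratio_range"])
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "CalibrationCurve":
        return cls.from_dict(json.loads(s))
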