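"""Net total age/period/cohort effect curves with identification bands.

A net total curve for one dimension combines a chosen linear effect (a
point in the bounded region) with that dimension's fitted nonlinear
deviations, on the mean-minutes scale: the intercept is included and
covariates and the other two dimensions sit at their weighted-effect zero,
so a curve value reads as expected minutes on an average day for the
average sample composition. The band is identification uncertainty only —
the envelope of the curve over the bounded range of the linear effect — not
sampling uncertainty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bounds import BoundedRegion
from .model import ThetaEstimates

DIMENSIONS = ("age", "period", "cohort")


@dataclass
class NetEffectCurve:
    """Per-group net total effect (minutes) with min/mid/max band."""

    dimension: str
    group_labels: list[str]
    values_mid: np.ndarray
    values_min: np.ndarray
    values_max: np.ndarray
    evaluated_at: str = (
        "intercept included; covariates and other dimensions at "
        "weighted-effect zero"
    )

    def __post_init__(self) -> None:
        if not (
            np.all(self.values_min <= self.values_mid + 1e-9)
            and np.all(self.values_mid <= self.values_max + 1e-9)
        ):
            raise ValueError("band must satisfy min <= mid <= max")

    def band_widths(self) -> np.ndarray:
        return self.values_max - self.values_min

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dimension": self.dimension,
                "group": self.group_labels,
                "mid": self.values_mid,
                "min": self.values_min,
                "max": self.values_max,
            }
        )


def net_total_curve(
    theta: ThetaEstimates,
    dimension: str,
    linear_value: float,
    include_intercept: bool = True,
) -> np.ndarray:
    """Net total curve for one dimension at a given linear effect value.

    value_g = [beta0] + linear_value * linear_g + sum_k coef_k * contrast_kg
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}")
    if not np.isfinite(linear_value):
        raise ValueError("linear_value must be finite")
    basis = theta.bases[dimension]
    out = linear_value * basis.linear.astype(float).copy()
    for coef, vec in zip(theta.nl_coefs(dimension), basis.nonlinear):
        out = out + coef * vec
    if include_intercept:
        out = out + theta.beta0
    return out


def net_effect_bands(
    theta: ThetaEstimates, region: BoundedRegion
) -> dict[str, NetEffectCurve]:
    """Mid/min/max net total curves for all three dimensions.

    The curves are affine in the linear effect, so the per-group envelope
    over the bounded range is attained at the range endpoints.
    """
    curves = {}
    for dim in DIMENSIONS:
        lo, hi = region.range_for(dim)
        mid = net_total_curve(theta, dim, region.mid_for(dim))
        c_lo = net_total_curve(theta, dim, lo)
        c_hi = net_total_curve(theta, dim, hi)
        curves[dim] = NetEffectCurve(
            dimension=dim,
            group_labels=list(theta.bases[dim].labels),
            values_mid=mid,
            values_min=np.minimum(c_lo, c_hi),
            values_max=np.maximum(c_lo, c_hi),
        )
    return curves


def summarize_curve(curve: NetEffectCurve) -> dict:
    """Argmin/argmax groups, extreme and endpoint mid-values, and the gap.

    Ties resolve to the lowest group index.
    """
    mid = curve.values_mid
    if mid.size == 0:
        raise ValueError("empty curve")
    i_min = int(np.argmin(mid))
    i_max = int(np.argmax(mid))
    labels = curve.group_labels or [str(i) for i in range(mid.size)]
    return {
        "dimension": curve.dimension,
        "argmin_group": labels[i_min],
        "argmax_group": labels[i_max],
        "min_mid": float(mid[i_min]),
        "max_mid": float(mid[i_max]),
        "first_mid": float(mid[0]),
        "last_mid": float(mid[-1]),
        "gap": float(mid[i_max] - mid[i_min]),
    }


def curves_to_frame(curves: dict[str, NetEffectCurve]) -> pd.DataFrame:
    return pd.concat([c.to_frame() for c in curves.values()], ignore_index=True)


def summaries_to_json(
    curves: dict[str, NetEffectCurve], path: str | Path
) -> dict:
    payload = {dim: summarize_curve(c) for dim, c in curves.items()}
    Path(path).write_text(json.dumps(payload, indent=2))
    return payload
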