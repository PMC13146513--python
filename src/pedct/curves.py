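"""Age-response curves for regional mean HU.

Gray-matter regions (whole parenchyma, caudate, cortical gray) follow power
laws ``y = a * x**b`` in age ``x`` (months); putamen, thalamus and white
matter are essentially age-flat and follow shallow linear trends
``y = b*x + intercept``; ventricular CSF is modelled as age-constant.
Lobar ROIs mix the slice's cortical-gray and white-matter curves with a
configurable area weight (default 60% gray / 40% white).

Ages are clamped to >= 1 month before evaluation (the power form diverges
at 0 and the youngest subjects scanned in practice are about a month old);
non-positive ages are rejected outright.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regions import RegionError

MIN_AGE_MONTHS = 1.0
MAX_AGE_MONTHS = 216.0  # 18 years

#: HU assigned to ventricular CSF at every age (ROI-method cohort median;
#: the ventricles show no age effect).
VENTRICLE_HU = 15.0

#: Gray fraction of lobar ROIs when mixing cortical GM and WM curves.
DEFAULT_LOBE_GM_WEIGHT = 0.6


class AgeDomainError(ValueError):
    """Age outside the model's domain (must be > 0 months)."""


@dataclass(frozen=True)
class AgeCurve:
    """One region's mean-HU trend versus age in months.

    ``form`` is ``"power"`` (y = a*x**b), ``"linear"`` (y = b*x + intercept)
    or ``"constant"`` (y = intercept).
    """

    form: str
    a: float = 0.0
    b: float = 0.0
    intercept: float = 0.0

    def __call__(self, age_months):
        age = np.asarray(age_months, dtype=float)
        if np.any(age <= 0):
            raise AgeDomainError("age must be > 0 months")
        x = np.clip(age, MIN_AGE_MONTHS, None)
        if self.form == "power":
            y = self.a * x**self.b
        elif self.form == "linear":
            y = self.b * x + self.intercept
        elif self.form == "constant":
            y = np.full_like(x, self.intercept)
        else:  # pragma: no cover - registry is fixed
            raise ValueError(f"unknown curve form {self.form!r}")
        return float(y) if np.isscalar(age_months) else y


@dataclass(frozen=True)
class MixtureCurve:
    """Area-weighted mixture of two curves (lobar gray/white composition)."""

    gm: AgeCurve
    wm: AgeCurve
    gm_weight: float = DEFAULT_LOBE_GM_WEIGHT

    def __call__(self, age_months):
        return self.gm_weight * self.gm(age_months) + (1.0 - self.gm_weight) * self.wm(
            age_months
        )


_P = lambda a, b: AgeCurve("power", a=a, b=b)
_L = lambda slope, intercept: AgeCurve("linear", b=slope, intercept=intercept)
_C = AgeCurve("constant", intercept=VENTRICLE_HU)

# Fitted cohort trends: power form for parenchyma, caudate and cortical gray;
# shallow linear for putamen, thalamus and white matter.
_BASE_CURVES: dict[str, AgeCurve] = {
    "parenchyma_SL1": _P(26.424, 0.025),
    "parenchyma_SL2": _P(25.5, 0.0233),
    "CN": _P(28.394, 0.0211),
    "GM_SL1": _P(26.843, 0.0403),
    "GM_SL2": _P(26.713, 0.039),
    "PT": _L(0.0005, 30.23),
    "TM": _L(0.0011, 29.53),
    "WM_SL1": _L(-0.0031, 24.26),
    "WM_SL2": _L(0.0061, 23.086),
    "ventricle_SL1": _C,
    "ventricle_SL2": _C,
}

# The two SL1 white-matter probe sites share the SL1 WM trend.
_ALIASES = {
    "WM_SL1_anterior": "WM_SL1",
    "WM_SL1_posterior": "WM_SL1",
}

_LOBES = {
    "frontal_SL1": ("GM_SL1", "WM_SL1"),
    "temporal_SL1": ("GM_SL1", "WM_SL1"),
    "parietal_SL1": ("GM_SL1", "WM_SL1"),
    "occipital_SL1": ("GM_SL1", "WM_SL1"),
    "frontal_SL2": ("GM_SL2", "WM_SL2"),
    "parietal_SL2": ("GM_SL2", "WM_SL2"),
    "occipital_SL2": ("GM_SL2", "WM_SL2"),
}


def curve_registry(lobe_gm_weight: float = DEFAULT_LOBE_GM_WEIGHT):
    """Full region -> curve mapping, lobes built with the given GM weight."""
    reg: dict[str, AgeCurve | MixtureCurve] = dict(_BASE_CURVES)
    for alias, target in _ALIASES.items():
        reg[alias] = _BASE_CURVES[target]
    for lobe, (gm, wm) in _LOBES.items():
        reg[lobe] = MixtureCurve(_BASE_CURVES[gm], _BASE_CURVES[wm], lobe_gm_weight)
    return reg


_DEFAULT_REGISTRY = curve_registry()


def regional_mean_curve(region: str, age_months) -> float:
    """Deterministic noise-free mean HU of ``region`` at ``age_months``.

    Raises :class:`~pedct.regions.RegionError` for an unregistered region and
    :class:`AgeDomainError` for non-positive ages.
    """
    try:
        curve = _DEFAULT_REGISTRY[region]
    except KeyError:
        raise RegionError(f"no age curve registered for region {region!r}") from None
    return curve(age_months)


def noise_sd_for_r2(
    region: str,
    target_r2: float,
    age_lo: float = MIN_AGE_MONTHS,
    age_hi: float = MAX_AGE_MONTHS,
) -> float:
    """Additive-HU noise SD such that a log-log fit attains roughly ``target_r2``.

    For ages uniform on [age_lo, age_hi] and a power curve with exponent b,
    the log-scale signal variance is (b * SD(ln x))**2; additive HU noise of
    SD sigma contributes approximately (sigma / ybar)**2 on the log scale, so

        sigma = ybar * |b| * SD(ln x) * sqrt((1 - R2) / R2)

    Only meaningful for power-form regions with b != 0 and 0 < R2 < 1.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must be in (0, 1)")
    curve = _DEFAULT_REGISTRY.get(region)
    if curve is None:
        raise RegionError(f"no age curve registered for region {region!r}")
    if not isinstance(curve, AgeCurve) or curve.form != "power" or curve.b == 0:
        raise ValueError("R2 calibration applies to power-form curves only")
    x = np.linspace(age_lo, age_hi, 20001)
    sd_lnx = float(np.std(np.log(x)))
    ybar = float(np.mean(curve(x)))
    return ybar * abs(curve.b) * sd_lnx * np.sqrt((1.0 - target_r2) / target_r2)
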