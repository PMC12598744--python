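"""Dose-volume cost function, NTCP endpoint models and fractionation utilities.

The planning cost applies weighted penalties to healthy-tissue dose only
(target coverage is guaranteed by the SOBP extent and the aperture, so it is
deliberately absent from the cost):

    C = sum_i (w_i / M) sum_j V_{d_j}(OAR_i)            (DVH-area term, M = 20
                                                         levels at 5% steps of
                                                         the prescription)
      + w_mac * D2%(macula)   + w_od * D20%(optic disc)
      + w_cor * D20%(cornea)  + w_ret * V55GyRBE(retina)
      + w_cil * V27GyRBE(ciliary body) + w_lens * D5%(lens)

The macula and optic disc carry weight 3, all other OARs weight 1 by default.
The named dose-volume points are the published predictors of maculopathy,
optic neuropathy, neovascular glaucoma, secondary ischemic retinal detachment
and cataract; each is mapped to a toxicity probability through a
two-parameter logistic NTCP curve.  The logistic parameters are configuration
(placeholder defaults documented below), not fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dose import DVHCurve, DoseGrid, dose_at_volume, volume_at_dose
from .errors import AttributionError_, ConfigurationError

COST_OARS = ("macula", "optic_disc", "cornea", "retina", "ciliary_body", "lens")

#: number of DVH levels in the first cost term (V5, V10, ..., V100)
DVH_LEVELS_M = 20

#: multiplicative adjustment of published dose thresholds to the 4 x 15 GyRBE
#: fractionation scheme (applied to the retina/ciliary-body dose-volume points)
FRACTIONATION_ADJUSTMENT = 0.96


@dataclass
class MetricSet:
    """The clinically relevant dose-volume points of one evaluated plan."""

    dvh_sums: dict        # OAR -> S_i = (1/M) sum_j V_{d_j}, in [0, 100]
    d2_macula: float      # GyRBE
    d20_optic_disc: float
    d20_cornea: float
    v55_retina: float     # %
    v27_ciliary: float    # %
    d5_lens: float        # GyRBE

    def named(self) -> dict:
        return {"d2_macula": self.d2_macula, "d20_optic_disc": self.d20_optic_disc,
                "d20_cornea": self.d20_cornea, "v55_retina": self.v55_retina,
                "v27_ciliary": self.v27_ciliary, "d5_lens": self.d5_lens}

    def as_row(self) -> dict:
        row = {f"s_{k}": v for k, v in self.dvh_sums.items()}
        row.update(self.named())
        return row


@dataclass
class WeightConfig:
    """Cost-function weights; ``first_term`` defaults to the per-OAR weights."""

    oar: dict = field(default_factory=lambda: {
        "macula": 3.0, "optic_disc": 3.0, "cornea": 1.0,
        "retina": 1.0, "ciliary_body": 1.0, "lens": 1.0})
    first_term: dict | None = None

    def __post_init__(self):
        if self.first_term is None:
            self.first_term = dict(self.oar)
        for w in list(self.oar.values()) + list(self.first_term.values()):
            if w < 0:
                raise ConfigurationError("cost weights must be non-negative")

    def scaled(self, c: float) -> "WeightConfig":
        return WeightConfig(oar={k: c * v for k, v in self.oar.items()},
                            first_term={k: c * v for k, v in self.first_term.items()})


def metrics_from_dvhs(curves: dict[str, DVHCurve], prescription: float = 60.0,
                      levels_m: int = DVH_LEVELS_M) -> MetricSet:
    """MetricSet from per-OAR DVH curves (exact order-statistic conventions)."""
    missing = [o for o in COST_OARS if o not in curves]
    if missing:
        raise AttributionError_(f"missing OAR DVHs: {missing}")
    d_levels = prescription * np.arange(1, levels_m + 1) / levels_m
    sums = {oar: float(np.mean(curves[oar].volumes_at(d_levels))) for oar in COST_OARS}
    return MetricSet(
        dvh_sums=sums,
        d2_macula=dose_at_volume(curves["macula"], 2.0),
        d20_optic_disc=dose_at_volume(curves["optic_disc"], 20.0),
        d20_cornea=dose_at_volume(curves["cornea"], 20.0),
        v55_retina=volume_at_dose(curves["retina"], 55.0),
        v27_ciliary=volume_at_dose(curves["ciliary_body"], 27.0),
        d5_lens=dose_at_volume(curves["lens"], 5.0),
    )


def extract_metrics(grid: DoseGrid, prescription: float | None = None) -> MetricSet:
    """MetricSet from a dose grid with OAR masks."""
    rx = grid.prescription if prescription is None else prescription
    curves = {}
    for oar in COST_OARS:
        if oar not in grid.masks:
            raise AttributionError_(f"dose grid has no mask for OAR '{oar}'")
        curves[oar] = DVHCurve.from_doses(oar, grid.structure_dose(oar))
    return metrics_from_dvhs(curves, prescription=rx)


def cost(metrics: MetricSet, weights: WeightConfig | None = None) -> float:
    """Weighted healthy-tissue penalty of one plan (dimensionless)."""
    w = weights or WeightConfig()
    c = sum(w.first_term[oar] * metrics.dvh_sums[oar] for oar in COST_OARS)
    c += w.oar["macula"] * metrics.d2_macula
    c += w.oar["optic_disc"] * metrics.d20_optic_disc
    c += w.oar["cornea"] * metrics.d20_cornea
    c += w.oar["retina"] * metrics.v55_retina
    c += w.oar["ciliary_body"] * metrics.v27_ciliary
    c += w.oar["lens"] * metrics.d5_lens
    return float(c)


# ---------------------------------------------------------------------------
# NTCP
# ---------------------------------------------------------------------------

ENDPOINTS = ("maculopathy", "optic_neuropathy", "nvg", "retinal_detachment", "cataract")


@dataclass
class NTCPModelParams:
    """Two-parameter logistic dose-response for one toxicity endpoint.

    NTCP(m) = 1 / (1 + exp(-(m - m50) / k)); ``metric`` names the MetricSet
    field feeding the curve.  ``threshold_scale`` optionally rescales m50 for a
    different fractionation scheme (the published 0.96 adjustment).
    """

    endpoint: str
    metric: str
    m50: float
    k: float
    threshold_scale: float = 1.0

    def __post_init__(self):
        if self.k <= 0:
            raise ConfigurationError("NTCP slope parameter k must be > 0")

    def effective_m50(self) -> float:
        return self.m50 * self.threshold_scale


def default_ntcp_params() -> dict[str, NTCPModelParams]:
    """Placeholder logistic parameters: m50 at 80% of each metric's scale
    (60 GyRBE prescription for dose metrics, 100% for volume metrics) with a
    visibly sloped curve.  These are configuration, not published fits."""
    return {
        "maculopathy": NTCPModelParams("maculopathy", "d2_macula", m50=48.0, k=6.0),
        "optic_neuropathy": NTCPModelParams("optic_neuropathy", "d20_optic_disc",
                                            m50=48.0, k=6.0),
        "nvg": NTCPModelParams("nvg", "d20_cornea", m50=48.0, k=6.0),
        "retinal_detachment": NTCPModelParams("retinal_detachment", "v55_retina",
                                              m50=80.0, k=10.0),
        "cataract": NTCPModelParams("cataract", "v27_ciliary", m50=80.0, k=10.0),
    }


def ntcp(metric_value: float, params: NTCPModelParams) -> float:
    """Toxicity probability in (0, 1) for a metric value."""
    x = (metric_value - params.effective_m50()) / params.k
    return float(1.0 / (1.0 + np.exp(-x)))


def ntcp_profile(metrics: MetricSet, params: dict[str, NTCPModelParams] | None = None
                 ) -> dict[str, float]:
    """All five endpoint probabilities, in percent."""
    params = params or default_ntcp_params()
    named = metrics.named()
    return {ep: 100.0 * ntcp(named[p.metric], p) for ep, p in params.items()}


def adjust_dose_threshold(dose: float, factor: float = FRACTIONATION_ADJUSTMENT) -> float:
    """Rescale a published dose threshold to the local fractionation scheme."""
    return dose * factor


def scaled_ntcp_params(params: dict[str, NTCPModelParams],
                       factor: float = FRACTIONATION_ADJUSTMENT,
                       endpoints: tuple = ("retinal_detachment", "cataract")
                       ) -> dict[str, NTCPModelParams]:
    """Apply the fractionation threshold adjustment to selected endpoints."""
    return {ep: (replace(p, threshold_scale=factor) if ep in endpoints else p)
            for ep, p in params.items()}


# ---------------------------------------------------------------------------
# Fractionation / BED
# ---------------------------------------------------------------------------

@dataclass
class FractionationScheme:
    """n fractions of d GyRBE each; alpha/beta in Gy (1 for ocular tissue)."""

    n: int
    d: float
    alpha_beta: float = 1.0

    def __post_init__(self):
        if self.n < 1 or self.d <= 0:
            raise ConfigurationError("need n >= 1 fractions of positive dose")
        if self.alpha_beta <= 0:
            raise ConfigurationError("alpha/beta must be positive")


def bed(scheme: FractionationScheme) -> float:
    """Biologically effective dose BED = n d (1 + d / (alpha/beta)), GyRBE."""
    return scheme.n * scheme.d * (1.0 + scheme.d / scheme.alpha_beta)


def relative_bed(a: FractionationScheme, b: FractionationScheme) -> float:
    """BED(a) / BED(b)."""
    return bed(a) / bed(b)
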