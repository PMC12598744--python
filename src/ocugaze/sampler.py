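"""ML-guided gaze sampling, candidate evaluation loop and continuous 2D maps.

The sampling procedure explores the feasible disk of gaze fixation points
(polar <= 25 deg on the plane 132.5 mm upstream of the isocentre) in five
steps: (1) the predicted fixation point defines a denser region of 50 mm
radius; (2) dart-throwing Poisson-disk samples with 9 mm minimum spacing fill
that region and enter a FIFO queue nearest-to-prediction first; (3) the
remaining sparser region is filled at 25 mm spacing (keeping 9 mm to dense
points) and appended after all dense entries; (4) each queued candidate is
oriented, checked for treatability, and its dose / cost / NTCP evaluated in
order; (5) the scattered evaluations are interpolated to continuous maps of
cost or any NTCP endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from .cost_ntcp import (COST_OARS, MetricSet, NTCPModelParams, WeightConfig,
                        cost as cost_fn, default_ntcp_params, extract_metrics,
                        metrics_from_dvhs, ntcp_profile)
from .dose import (DEFAULT_GRID_SHAPE, DEFAULT_GRID_SPACING, DVHCurve, BeamSpec,
                   compute_dose_grid, derive_beam, dose_at_points, grid_origin_for)
from .errors import ConfigurationError, FeasibilityError, MapError, OptimizationError, TreatabilityError
from .eye_model import EyeModel, orient_model
from .fixation import FixationPoint, angles_from_plane
from .geometry import PLANE_DISTANCE, POLAR_MAX, circle_lattice, feasible_disk_radius
from .ml_gaze import ForestEnsemble, extract_features, predict


@dataclass
class SamplerConfig:
    """Geometry and budget of the two-density dart-throwing sampler."""

    dense_radius: float = 50.0    # mm, extent of the denser region around the prediction
    dense_spacing: float = 9.0    # mm, minimum pairwise distance in the dense region
    sparse_spacing: float = 25.0  # mm, minimum spacing among sparse points
    cross_spacing: float = 9.0    # mm, minimum sparse-to-dense distance
    polar_max: float = POLAR_MAX
    plane_distance: float = PLANE_DISTANCE
    dense_attempts: int = 200     # dart throws per region (fixed budget)
    sparse_attempts: int = 150
    seed: int = 0
    max_evaluations: int | None = None
    early_stop_patience: int | None = None

    def __post_init__(self):
        if self.dense_spacing >= self.sparse_spacing:
            raise ConfigurationError("dense spacing must be below sparse spacing")
        if self.dense_radius <= self.dense_spacing:
            raise ConfigurationError("dense radius must exceed dense spacing")

    @property
    def disk_radius(self) -> float:
        return feasible_disk_radius(self.plane_distance, self.polar_max)


def sample_candidates(prediction: FixationPoint, config: SamplerConfig | None = None,
                      rng: np.random.Generator | None = None) -> list[FixationPoint]:
    """Ordered candidate queue: dense entries (nearest to the prediction first)
    followed by sparse entries; all spacing constraints enforced by rejection."""
    cfg = config or SamplerConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    rmax = cfg.disk_radius
    pred = prediction.xy
    if prediction.r > rmax + 1e-9:
        raise FeasibilityError("prediction lies outside the feasible disk")

    # the first dart is the prediction itself: it is the single most likely
    # treatment-viable fixation point and anchors the dense region
    dense: list[np.ndarray] = [pred.copy()]
    for _ in range(cfg.dense_attempts):
        p = pred + _uniform_in_disk(rng, cfg.dense_radius)
        if p @ p > rmax * rmax:
            continue                      # dense region clipped at the disk edge
        if dense and np.min(np.linalg.norm(np.array(dense) - p, axis=1)) < cfg.dense_spacing:
            continue
        dense.append(p)

    sparse: list[np.ndarray] = []
    dense_arr = np.array(dense) if dense else np.empty((0, 2))
    for _ in range(cfg.sparse_attempts):
        p = _uniform_in_disk(rng, rmax)
        if np.linalg.norm(p - pred) <= cfg.dense_radius:
            continue                      # belongs to the dense region
        if dense_arr.size and np.min(np.linalg.norm(dense_arr - p, axis=1)) < cfg.cross_spacing:
            continue
        if sparse and np.min(np.linalg.norm(np.array(sparse) - p, axis=1)) < cfg.sparse_spacing:
            continue
        sparse.append(p)

    dense.sort(key=lambda p: float(np.linalg.norm(p - pred)))
    queue = dense + sparse
    return [angles_from_plane(p[0], p[1], cfg.plane_distance, cfg.polar_max)
            for p in queue]


def _uniform_in_disk(rng: np.random.Generator, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform())
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([r * np.cos(phi), r * np.sin(phi)])


# ---------------------------------------------------------------------------
# Candidate evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationRecord:
    """Outcome of evaluating one candidate gaze fixation point."""

    fixation: FixationPoint
    treatable: bool
    index: int
    cost: float | None = None
    metrics: MetricSet | None = None
    ntcp: dict | None = None
    reason: str | None = None


@dataclass
class EvaluationSettings:
    """Shared dose/metric settings for the evaluation loop."""

    weights: WeightConfig = field(default_factory=WeightConfig)
    ntcp_params: dict | None = None
    prescription: float = 60.0
    grid_shape: tuple = DEFAULT_GRID_SHAPE
    grid_spacing: float = DEFAULT_GRID_SPACING
    beam_kwargs: dict = field(default_factory=dict)
    fast: bool = True   # evaluate dose only at OAR mask voxels

    def params(self) -> dict[str, NTCPModelParams]:
        return self.ntcp_params or default_ntcp_params()


def evaluate_fixation(model: EyeModel, fixation: FixationPoint,
                      settings: EvaluationSettings | None = None,
                      index: int = 0) -> EvaluationRecord:
    """Orient, derive the beam, compute dose metrics, cost and NTCPs for one
    candidate; untreatable orientations are recorded, not raised."""
    s = settings or EvaluationSettings()
    oriented, _ = orient_model(model, fixation)
    try:
        beam = derive_beam(oriented, prescription=s.prescription, **s.beam_kwargs)
    except TreatabilityError as exc:
        return EvaluationRecord(fixation=fixation, treatable=False, index=index,
                                reason=str(exc))
    if s.fast:
        metrics = _fast_metrics(oriented, beam, s)
    else:
        grid = compute_dose_grid(oriented, beam, shape=s.grid_shape,
                                 spacing=s.grid_spacing)
        metrics = extract_metrics(grid)
    c = cost_fn(metrics, s.weights)
    prof = ntcp_profile(metrics, s.params())
    return EvaluationRecord(fixation=fixation, treatable=True, index=index,
                            cost=c, metrics=metrics, ntcp=prof)


def _fast_metrics(oriented: EyeModel, beam: BeamSpec, s: EvaluationSettings) -> MetricSet:
    """Metrics via dose evaluated only at each OAR's occupied voxel centres.

    Identical to the full-grid path: voxelization and the dose model are the
    same; voxels outside every OAR mask contribute to no metric.
    """
    origin = grid_origin_for(oriented, s.grid_shape, s.grid_spacing)
    shape = np.array(s.grid_shape)
    curves = {}
    for oar in COST_OARS:
        pts = oriented.points(oar)
        idx = np.floor((pts - origin) / s.grid_spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        idx = np.unique(idx[ok], axis=0)
        centres = origin + (idx + 0.5) * s.grid_spacing
        doses = dose_at_points(centres, beam, oriented.globe_centre,
                               oriented.globe_radius)
        curves[oar] = DVHCurve.from_doses(oar, doses)
    return metrics_from_dvhs(curves, prescription=s.prescription)


@dataclass
class OptimizationResult:
    best: EvaluationRecord
    records: list[EvaluationRecord]
    prediction: FixationPoint

    @property
    def treatable_records(self) -> list[EvaluationRecord]:
        return [r for r in self.records if r.treatable]


def run_optimization(model: EyeModel, ensemble: ForestEnsemble | None = None,
                     prediction: FixationPoint | None = None,
                     settings: EvaluationSettings | None = None,
                     config: SamplerConfig | None = None) -> OptimizationResult:
    """Full guided optimization for one patient.

    The prediction comes from the trained ensemble unless explicitly
    overridden.  Candidates are processed in FIFO order; the best record is the
    treatable candidate of minimum cost (ties: smaller polar angle, then
    smaller azimuth).  Optional early stopping after ``early_stop_patience``
    consecutive non-improving treatable evaluations.
    """
    cfg = config or SamplerConfig()
    s = settings or EvaluationSettings()
    if prediction is None:
        if ensemble is None:
            raise ConfigurationError("need a trained ensemble or a prediction override")
        prediction = predict(ensemble, extract_features(model),
                             cfg.plane_distance, cfg.polar_max)
    rng = np.random.default_rng(cfg.seed)
    queue = sample_candidates(prediction, cfg, rng)
    if cfg.max_evaluations is not None:
        queue = queue[:cfg.max_evaluations]
    records: list[EvaluationRecord] = []
    best: EvaluationRecord | None = None
    since_improvement = 0
    for i, fx in enumerate(queue):
        rec = evaluate_fixation(model, fx, s, index=i)
        records.append(rec)
        if rec.treatable:
            if best is None or _better(rec, best):
                best = rec
                since_improvement = 0
            else:
                since_improvement += 1
            if (cfg.early_stop_patience is not None
                    and since_improvement >= cfg.early_stop_patience):
                break
    if best is None:
        reasons = {r.index: r.reason for r in records}
        raise OptimizationError(
            f"no treatable candidate among {len(records)} evaluations", reasons=reasons)
    return OptimizationResult(best=best, records=records, prediction=prediction)


def _better(a: EvaluationRecord, b: EvaluationRecord) -> bool:
    if a.cost != b.cost:
        return a.cost < b.cost
    if a.fixation.polar != b.fixation.polar:
        return a.fixation.polar < b.fixation.polar
    return a.fixation.azimuth < b.fixation.azimuth


def exhaustive_candidates(spacing: float = 2.0,
                          plane_distance: float = PLANE_DISTANCE,
                          polar_max: float = POLAR_MAX) -> list[FixationPoint]:
    """Regular-lattice reference sampling of the whole feasible disk
    (brute-force baseline against which the guided sampler is measured)."""
    pts = circle_lattice(feasible_disk_radius(plane_distance, polar_max), spacing)
    return [angles_from_plane(x, y, plane_distance, polar_max) for x, y in pts]


# ---------------------------------------------------------------------------
# Continuous 2D maps
# ---------------------------------------------------------------------------

MAP_QUANTITIES = ("cost", "maculopathy", "optic_neuropathy", "nvg",
                  "retinal_detachment", "cataract")


@dataclass
class GazeMap:
    """Piecewise-linear interpolant of a scalar quantity over the fixation plane;
    nearest-sample value outside the convex hull of the samples."""

    quantity: str
    points: np.ndarray    # (n, 2) sample locations, mm
    values: np.ndarray    # (n,)
    _linear: LinearNDInterpolator = field(repr=False, default=None)
    _nearest: NearestNDInterpolator = field(repr=False, default=None)

    def __call__(self, x, y):
        xy = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
        v = self._linear(xy)
        miss = np.isnan(v)
        if np.any(miss):
            v[miss] = self._nearest(xy[miss])
        return v if v.size > 1 else float(v[0])

    def raster(self, spacing: float = 2.0, radius: float | None = None):
        """Regular raster over the feasible disk: (x, y, value) columns."""
        r = radius if radius is not None else feasible_disk_radius()
        pts = circle_lattice(r, spacing)
        vals = self(pts[:, 0], pts[:, 1])
        return np.column_stack([pts, np.atleast_1d(vals)])


def build_map(records: list[EvaluationRecord], quantity: str = "cost") -> GazeMap:
    """Continuous map of cost or one NTCP endpoint from treatable records."""
    if quantity not in MAP_QUANTITIES:
        raise MapError(f"unknown map quantity '{quantity}' (choose from {MAP_QUANTITIES})")
    recs = [r for r in records if r.treatable]
    if len(recs) < 3:
        raise MapError(f"need at least 3 treatable records to build a map, got {len(recs)}")
    pts = np.array([[r.fixation.x, r.fixation.y] for r in recs])
    if quantity == "cost":
        vals = np.array([r.cost for r in recs])
    else:
        vals = np.array([r.ntcp[quantity] for r in recs])
    lin = LinearNDInterpolator(pts, vals)
    near = NearestNDInterpolator(pts, vals)
    return GazeMap(quantity=quantity, points=pts, values=vals,
                   _linear=lin, _nearest=near)
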