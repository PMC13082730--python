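"""End-to-end inference runs, multi-cell averaging, and reference maps.

``run_single_cell`` chains the whole pipeline for one cell pair:
triangulate markers, compute deformation gradients and the sensitivity
filter, estimate curvatures from the wall outline, recover tensions,
reduce everything to the axisymmetric coordinate alpha, infer the bulk
modulus per triangle, filter non-physical values, and bin.

On top of single runs the module provides the protocols of the
robustness study: a second triangulation on the same cell (more data
without more samples), bin-wise averaging over cohorts, the error versus
sample-size curve with knee detection, and the endpoint-ratio /
error reference maps over grids of ground-truth ``(K_side, K_tip)``
pairs that calibrate when an inferred gradient can be trusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import curvature as cv
from . import shell_model as sm
from .axis_reduction import (BinnedProfile, bin_by_alpha, bin_points_by_alpha,
                             default_bin_edges, directional_stretches,
                             optimize_long_axis, profile_endpoint_values,
                             triangle_frames)
from .deformation import compute_patches, filter_by_gamma
from .forward_simulator import (CellConfigurationPair, HyphoidSpec, ModulusProfile,
                                NoiseSpec, generate_cohort, resample_markers,
                                solve_turgid_outline)
from .surface_mesh import (build_mesh, delaunay_connectivity, estimate_tip_radius,
                           mean_triangle_area, project_markers)

__all__ = [
    "MESH_CLASSES",
    "RunConfig",
    "InferenceRun",
    "run_single_cell",
    "two_triangulation_augment",
    "average_cells",
    "error_vs_n_curve",
    "knee_point",
    "evaluate_map_node",
    "build_reference_map",
    "error_metrics",
]

#: Named triangulation classes: (number of markers, minimum marker
#: distance in radius units).  Fewer, farther markers give the larger
#: mean nondimensional triangle area.
MESH_CLASSES = {
    "small": (155, 0.12),
    "medium": (110, 0.22),
    "large": (55, 0.42),
}


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a single-cell inference run."""

    mesh_class: str = "small"
    n_markers: Optional[int] = None
    min_dist: Optional[float] = None
    bin_edges: np.ndarray = field(default_factory=default_bin_edges)
    gamma_percentile: float = 90.0
    min_compactness: float = 0.2
    pitch_fraction: float = cv.DEFAULT_PITCH_FRACTION
    fd_spacing: int = 3
    tension_configuration: str = "turgid"  # outline cloud feeding curvature/tensions
    P: float = 1.0

    def marker_params(self) -> Tuple[int, float]:
        if self.n_markers is not None and self.min_dist is not None:
            return self.n_markers, self.min_dist
        return MESH_CLASSES[self.mesh_class]


@dataclass
class InferenceRun:
    """Result of one single-cell inference."""

    profiles: Dict[str, BinnedProfile]
    truth_bins: Optional[BinnedProfile]
    eps_K: Optional[float]
    endpoint: Optional[Tuple[float, float]]
    mean_area: float
    counts: Dict[str, int]
    failed: bool = False
    config: Optional[RunConfig] = None

    @property
    def endpoint_ratio(self) -> Optional[float]:
        if self.endpoint is None:
            return None
        return self.endpoint[0] / self.endpoint[1]


def _truth_bins(pair: CellConfigurationPair, edges: np.ndarray) -> BinnedProfile:
    """Ground-truth K_h binned by alpha, area-weighted along the meridian."""
    st = pair.truth.stations(2049)
    ds = np.gradient(st["S"]) * st["lambda_s"]
    w = np.maximum(st["r_t"], 1e-6) * ds  # turgid surface-area weight
    return bin_points_by_alpha(st["alpha_deg"], st["K_h"], edges, weights=w)


def run_single_cell(pair: CellConfigurationPair, config: RunConfig = RunConfig(),
                    markers: Optional[Tuple[np.ndarray, np.ndarray]] = None,
                    _cell_cache: Optional[dict] = None) -> InferenceRun:
    """Run the full inference pipeline on one cell pair.

    ``markers`` may override the pair's marker sets (used by the
    two-triangulation protocol).  The run is deterministic given the
    pair and configuration.  ``_cell_cache`` (same dict across repeated
    triangulations of one cell) memoizes the marker-independent stages:
    axis, tip radius and the wall-curvature field.
    """
    L = pair.radius
    scheme = sm.NondimScheme(P=config.P, L_ref=L)
    mk_u = pair.markers_unturgid if markers is None else markers[0]
    mk_t = pair.markers_turgid if markers is None else markers[1]

    cloud = pair.outline_turgid if config.tension_configuration == "turgid" else pair.outline_unturgid
    cache = {} if _cell_cache is None else _cell_cache
    if "frame" not in cache:
        cache["frame"] = optimize_long_axis(cloud)
        cache["tip_r"] = estimate_tip_radius(cloud, cache["frame"])
    frame = cache["frame"]
    tip_r = cache["tip_r"]

    # --- mesh ---
    pts2d = project_markers(mk_t, frame, tip_radius=tip_r)
    faces = delaunay_connectivity(pts2d)
    mesh = build_mesh(mk_u, mk_t, faces, frame_turgid=frame,
                      min_compactness=config.min_compactness)
    mean_area, _ = mean_triangle_area(mesh, L)

    # --- deformation + sensitivity filter ---
    patches = compute_patches(mesh)
    gamma_keep = filter_by_gamma(
        np.where(mesh.usable, patches.gamma, np.inf), config.gamma_percentile)
    usable = mesh.usable & gamma_keep

    # --- curvature / tensions on the wall outline ---
    if "field" not in cache:
        cache["field"] = cv.curvature_field(cloud, frame, tip_r,
                                            pitch=config.pitch_fraction * L,
                                            fd_spacing=config.fd_spacing, L_ref=L)
    fieldc = cache["field"]
    kap_s = fieldc.kappa_s * L   # nondimensionalize
    kap_t = fieldc.kappa_theta * L
    with np.errstate(divide="ignore", invalid="ignore"):
        sig_s = config.P / (2.0 * kap_t)
        sig_t = sig_s * (2.0 - kap_s / kap_t)

    assigned = cv.assign_points_to_faces(cloud, mesh.pts_turgid, mesh.faces, mesh.mean_edge)
    means, alpha_ranges, pt_counts = cv.average_onto_triangles(
        {"kappa_s": kap_s, "kappa_theta": kap_t, "sigma_s": sig_s, "sigma_theta": sig_t},
        assigned, mesh.n_faces, point_valid=fieldc.valid, alpha_deg=fieldc.alpha_deg)
    has_points = pt_counts > 0
    usable &= has_points & np.isfinite(alpha_ranges[:, 0])

    # --- axisymmetric frames and directional stretches ---
    v_s, v_th, degen = triangle_frames(patches.dir1_turgid, patches.dir2_turgid,
                                       mesh.normals_turgid, mesh.centroids_turgid, frame.tip)
    usable &= ~degen
    stretch = directional_stretches(patches.F_inv, v_s, v_th)
    area_stretch = stretch.area_stretch

    # --- modulus inference + non-physical filter ---
    tensions = sm.TensionPair(sigma_s=means["sigma_s"], sigma_theta=means["sigma_theta"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        K_face = sm.infer_bulk_modulus(tensions, stretch, strict=False)
        K_area = sm.bulk_modulus_area_method(mesh.area_turgid, mesh.area_unturgid,
                                             tensions, strict=False)
    tol = 1.0 + sm.AREA_STRETCH_TOL  # singular exactly at unit area stretch
    physical = usable & (K_face > 0) & (area_stretch > tol)
    physical_area = usable & (K_area > 0) & (mesh.area_turgid > tol * mesh.area_unturgid)

    def prof(vals, mask):
        v = np.where(mask, vals, np.nan)
        return bin_by_alpha(v, alpha_ranges, config.bin_edges)

    def binned_inference(j_mask, j_vals, k_perface):
        """Bin tensions and area stretch over the filtered faces, then
        apply the bulk-modulus formula per bin.  Dividing by the binned
        area strain (rather than per face) keeps single near-singular
        triangles (area stretch just above 1) from injecting unbounded
        values into the profile; the per-face division is kept as the
        *_face profiles."""
        pj = prof(j_vals, j_mask)
        pss = prof(means["sigma_s"], j_mask)
        pst = prof(means["sigma_theta"], j_mask)
        with np.errstate(divide="ignore", invalid="ignore"):
            kmean = np.where(pj.mean > 1.0, (pss.mean + pst.mean) / (2.0 * (pj.mean - 1.0)), np.nan)
        pface = prof(k_perface, j_mask)
        ok = np.isfinite(kmean)
        return BinnedProfile(edges=pj.edges, mean=kmean, sd=pface.sd,
                             count=np.where(ok, pj.count, 0),
                             weight=np.where(ok, pj.weight, 0.0)), pface

    k_prof, k_face_prof = binned_inference(physical, area_stretch, K_face)
    area_ratio = mesh.area_turgid / mesh.area_unturgid
    k_area_prof, k_area_face_prof = binned_inference(physical_area, area_ratio, K_area)

    sigma_sum = means["sigma_s"] + means["sigma_theta"]
    profiles = {
        # filtered ingredients of the bulk-modulus inference, kept so
        # cohorts can pool fields across cells before the division
        "sigma_sum_phys": prof(sigma_sum, physical),
        "area_stretch_phys": prof(area_stretch, physical),
        "K_h": k_prof,
        "K_h_face": k_face_prof,
        "K_h_area": k_area_prof,
        "K_h_area_face": k_area_face_prof,
        "lambda_s": prof(stretch.lambda_s, usable),
        "lambda_theta": prof(stretch.lambda_theta, usable),
        "area_stretch": prof(area_stretch, usable),
        "kappa_s": prof(means["kappa_s"], usable),
        "kappa_theta": prof(means["kappa_theta"], usable),
        "sigma_s": prof(means["sigma_s"], usable),
        "sigma_theta": prof(means["sigma_theta"], usable),
    }
    counts = {
        "faces": int(mesh.n_faces),
        "usable": int(usable.sum()),
        "dropped_compactness": int((~mesh.usable).sum()),
        "dropped_gamma": int((mesh.usable & ~gamma_keep).sum()),
        "dropped_nonphysical": int((usable & ~physical).sum()),
        "wall_points_assigned": int((assigned >= 0).sum()),
    }

    truth = _truth_bins(pair, np.asarray(config.bin_edges)) if pair.truth is not None else None
    run = InferenceRun(profiles=profiles, truth_bins=truth, eps_K=None,
                       endpoint=None, mean_area=mean_area, counts=counts,
                       config=config)
    kprof = profiles["K_h"]
    if kprof.nonempty.sum() < 3:
        run.failed = True
        return run
    if truth is not None:
        run.eps_K = error_metrics(kprof, truth)["eps_K"]
    try:
        run.endpoint = profile_endpoint_values(kprof)
    except ValueError:
        run.failed = True
    return run


def two_triangulation_augment(pair: CellConfigurationPair, config: RunConfig,
                              rng: np.random.Generator) -> List[InferenceRun]:
    """Two independent triangulations of the same cell.

    The two marker subsets are drawn independently (not necessarily
    disjoint); outline data and ground truth are shared.
    """
    n, d = config.marker_params()
    runs = []
    cache: dict = {}
    for _ in range(2):
        p = resample_markers(pair, rng, n_subset=n, min_dist=d)
        runs.append(run_single_cell(p, config, _cell_cache=cache))
    return runs


def _mean_over_runs(good: Sequence[InferenceRun], key: str, min_presence: float):
    edges = good[0].profiles[key].edges
    stack = np.stack([r.profiles[key].mean for r in good])
    present = np.stack([r.profiles[key].nonempty for r in good])
    keep = present.mean(axis=0) >= min_presence
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean = np.where(keep, np.nanmean(np.where(present, stack, np.nan), axis=0), np.nan)
        sd = np.where(keep, np.nanstd(np.where(present, stack, np.nan), axis=0), np.nan)
    count = np.where(keep, present.sum(axis=0), 0)
    return BinnedProfile(edges=edges, mean=mean, sd=sd, count=count,
                         weight=count.astype(float))


def average_cells(runs: Sequence[InferenceRun], key: str = "K_h",
                  min_presence: float = 0.5):
    """Bin-wise unweighted mean profile across runs, with its error.

    For the bulk modulus the cohort pools the measured fields first: the
    filtered per-run tension-sum and area-stretch bins are averaged
    across runs and the inference formula is applied once per bin.
    Averaging before the division keeps bins that hold only a handful of
    triangles in any single run (the apex bins of coarse meshes) from
    injecting near-singular reciprocals into the cohort mean; it is also
    what exposes the filtering-induced underestimation at the tip
    cleanly.  Other keys are plain bin-wise means of the per-run
    profiles.

    Bins present in fewer than ``min_presence`` of the successful runs
    are dropped.  Returns ``(profile, eps_K_bar)``; the error compares
    the averaged profile to the (shared) ground truth.
    """
    good = [r for r in runs if not r.failed]
    if not good:
        raise ValueError("no successful runs to average")
    truth = good[0].truth_bins
    if key == "K_h" and "sigma_sum_phys" in good[0].profiles:
        ssum = _mean_over_runs(good, "sigma_sum_phys", min_presence)
        jbar = _mean_over_runs(good, "area_stretch_phys", min_presence)
        kface = _mean_over_runs(good, "K_h_face", 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            kmean = np.where(jbar.mean > 1.0, ssum.mean / (2.0 * (jbar.mean - 1.0)), np.nan)
        ok = np.isfinite(kmean)
        avg = BinnedProfile(edges=jbar.edges, mean=kmean, sd=kface.sd,
                            count=np.where(ok, jbar.count, 0),
                            weight=np.where(ok, jbar.weight, 0.0))
    else:
        avg = _mean_over_runs(good, key, min_presence)
    eps = error_metrics(avg, truth)["eps_K"] if truth is not None else None
    return avg, eps


def error_metrics(profile: BinnedProfile, truth: BinnedProfile,
                  true_ratio: Optional[float] = None) -> Dict[str, float]:
    """Error summaries of a binned inference against the ground truth.

    ``eps_K`` is the mean over usable bins of |inferred - true| / true;
    when ``true_ratio`` is given, the signed and absolute endpoint-ratio
    errors are included as well.
    """
    both = profile.nonempty & truth.nonempty & np.isfinite(profile.mean)
    if not np.any(both):
        return {"eps_K": np.nan}
    rel = np.abs(profile.mean[both] - truth.mean[both]) / truth.mean[both]
    out = {"eps_K": float(rel.mean())}
    if true_ratio is not None:
        ks, kt = profile_endpoint_values(profile)
        signed = (ks / kt - true_ratio) / true_ratio
        out["ratio"] = ks / kt
        out["ratio_error_signed"] = float(signed)
        out["ratio_error_abs"] = float(abs(signed))
    return out


def error_vs_n_curve(cell_runs: Sequence[Sequence[InferenceRun]], n_max: int,
                     repeats: int, rng: np.random.Generator):
    """Mean and SD of the averaged error at increasing sample sizes.

    ``cell_runs[i]`` holds the run(s) of cell ``i`` (one or two
    triangulations).  For each ``n`` in ``1..n_max``, ``repeats`` random
    subsets of ``n`` cells (without replacement) are averaged.
    Returns ``(n_values, mean_error, sd_error)``.
    """
    n_cells = len(cell_runs)
    if n_max > n_cells:
        raise ValueError("n_max exceeds the cohort size")
    ns = np.arange(1, n_max + 1)
    mean_err = np.full(len(ns), np.nan)
    sd_err = np.full(len(ns), np.nan)
    for i, n in enumerate(ns):
        errs = []
        for _ in range(repeats):
            pick = rng.choice(n_cells, size=n, replace=False)
            runs = [r for j in pick for r in cell_runs[j]]
            try:
                _, eps = average_cells(runs)
            except ValueError:
                continue
            errs.append(eps)
        if errs:
            mean_err[i] = float(np.mean(errs))
            sd_err[i] = float(np.std(errs))
    return ns, mean_err, sd_err


def knee_point(n_values: np.ndarray, errors: np.ndarray,
               flat_tol: float = 0.02) -> Tuple[int, float, bool]:
    """Diminishing-returns point of an error-vs-n curve.

    Kneedle-style: after normalizing both axes to [0, 1], the knee is the
    point of maximum distance from the secant through the endpoints.  A
    curve whose maximum distance is below ``flat_tol`` (straight line) has
    no knee; the endpoint is returned with ``defined = False``.

    Returns ``(n_knee, error_at_knee, defined)``.
    """
    x = np.asarray(n_values, dtype=float)
    y = np.asarray(errors, dtype=float)
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("curve too short for knee detection")
    xn = (x - x[0]) / (x[-1] - x[0])
    span = y.max() - y.min()
    if span <= 0:
        return int(x[-1]), float(y[-1]), False
    yn = (y - y.min()) / span
    # distance from the secant through the endpoints (scale-invariant)
    d = np.abs((yn[-1] - yn[0]) * xn - (xn[-1] - xn[0]) * yn + xn[-1] * yn[0] - yn[-1] * xn[0])
    d /= np.hypot(yn[-1] - yn[0], xn[-1] - xn[0])
    i = int(np.argmax(d))
    if d[i] < flat_tol:
        return int(x[-1]), float(y[-1]), False
    return int(x[i]), float(y[i]), True


def evaluate_map_node(
    K_side: float,
    K_tip: float,
    spec: HyphoidSpec,
    noise: NoiseSpec,
    config: RunConfig,
    repeats: int = 10,
    n_cells: int = 10,
    seed: Optional[int] = None,
    profile_kind: str = "nonlinear",
    nu: float = 0.5,
) -> Dict[str, float]:
    """Repeated standardized n-cell averaging at one ground-truth node.

    Gradient nodes use the nonlinear profile; diagonal nodes
    (``K_side == K_tip``) are constant-profile cells.  Each repeat draws a
    fresh cohort (two triangulations per cell), averages, and records the
    endpoint ratio and mean profile error; the node reports the means
    over repeats.
    """
    if K_side == K_tip:
        profile = ModulusProfile.constant(K_side, nu=nu)
    else:
        profile = ModulusProfile(kind=profile_kind, K_side=K_side, K_tip=K_tip, nu=nu)
    ss = np.random.SeedSequence(seed)
    n_mk, d_mk = config.marker_params()
    solution = solve_turgid_outline(spec, profile)
    true_ratio = K_side / K_tip
    ratios, errs, ratio_errs = [], [], []
    for rep_seed in ss.spawn(repeats):
        rng = np.random.default_rng(rep_seed)
        cohort = generate_cohort(n_cells, spec, profile, noise,
                                 seed=rep_seed.generate_state(1)[0] % (2**31),
                                 n_subset=n_mk, min_dist=d_mk)
        runs = []
        for cell in cohort:
            runs.extend(two_triangulation_augment(cell, config, rng))
        try:
            avg, eps = average_cells(runs)
            ks, kt = profile_endpoint_values(avg)
        except ValueError:
            continue
        ratios.append(ks / kt)
        errs.append(eps)
        ratio_errs.append((ks / kt - true_ratio) / true_ratio)
    if not ratios:
        return {"ratio": np.nan, "eps_K_bar": np.nan, "ratio_error": np.nan,
                "n_repeats": 0}
    return {
        "ratio": float(np.mean(ratios)),
        "ratio_sd": float(np.std(ratios)),
        "eps_K_bar": float(np.mean(errs)),
        "ratio_error": float(np.mean(np.abs(ratio_errs))),
        "ratio_error_signed": float(np.mean(ratio_errs)),
        "n_repeats": len(ratios),
    }


def build_reference_map(
    K_side_values: Sequence[float],
    spec: HyphoidSpec,
    noise: NoiseSpec,
    config: RunConfig,
    repeats: int = 10,
    n_cells: int = 10,
    seed: Optional[int] = None,
    K_tip_values: Optional[Sequence[float]] = None,
):
    """Endpoint-ratio and error maps over a (K_side, K_tip) grid.

    The grid is restricted to ``K_side >= K_tip`` (gradients decrease
    toward the tip); the diagonal holds constant-profile cells with true
    ratio 1.  Returns a list of node records; failed nodes are recorded
    as gaps (NaN values).
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for ks in K_side_values:
        tips = [kt for kt in (K_tip_values or K_side_values) if kt <= ks]
        for kt, node_seed in zip(tips, ss.spawn(len(tips))):
            res = evaluate_map_node(ks, kt, spec, noise, config, repeats=repeats,
                                    n_cells=n_cells,
                                    seed=node_seed.generate_state(1)[0] % (2**31))
            rows.append({"K_side": ks, "K_tip": kt, "true_ratio": ks / kt, **res})
    return rows
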