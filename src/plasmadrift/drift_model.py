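"""Cluster-based kinetic drift modeling of pre-centrifugation delay effects.

Whole blood keeps metabolizing between draw and centrifugation, so plasma
feature intensities drift with the pre-centrifugation delay time.  For one
storage temperature this module:

1. converts intensities to per-subject fold-changes relative to each
   subject's own reference-time (default 1 h) sample,
2. excludes features whose drift is irreproducible between subjects
   (low median pairwise between-subject correlation of log fold-change
   profiles, yet clearly non-flat),
3. clusters the remaining subject-averaged drift profiles by hierarchical
   agglomerative clustering with automatic cluster-number selection, and
4. fits each cluster an anchored natural cubic spline drift function
   ``g_c(t)`` with ``g_c(t_ref) = 1``.

The drift functions feed the multiplicative correction in
:mod:`plasmadrift.drift_correct`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import CubicSpline, PPoly, make_smoothing_spline
from sklearn.metrics import silhouette_score

from .dataio import FeatureTable


class DriftModelError(ValueError):
    pass


@dataclass
class DriftConfig:
    """Tunable parameters of drift-model fitting.

    t_ref:
        Reference delay time in hours to which data are anchored (1 h, the
        earliest practically achievable needle-to-centrifuge delay).
    repro_threshold:
        Minimum median pairwise between-subject Pearson correlation of log
        fold-change profiles for a non-flat feature to count as reproducible.
    flat_tol:
        A feature whose mean log fold-change stays within +/- flat_tol at
        every time point is considered flat ("stable") and is kept even when
        its reproducibility is low (flat profiles have no correlatable shape).
    k_range:
        Inclusive range of cluster numbers searched; the number is chosen by
        maximum mean silhouette width, ties broken toward fewer clusters.
    """

    t_ref: float = 1.0
    repro_threshold: float = 0.5
    flat_tol: float = 0.05
    k_range: tuple[int, int] = (2, 30)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        return d


@dataclass
class DriftProfile:
    """Per-feature drift profile: fold-changes relative to the t_ref sample."""

    feature_id: str
    #: subjects x time points fold-changes, index = subject ids
    per_subject_profile: pd.DataFrame
    #: subject-averaged fold-change per time point (1.0 at t_ref by construction)
    mean_profile: pd.Series
    #: median pairwise between-subject Pearson correlation of log fold-changes
    reproducibility: float


class DriftFunction:
    """Anchored, positivity-guarded drift curve g_c(t) with boundary clamping.

    Evaluations outside the fitted time range clamp to the boundary value:
    extrapolating a cubic outside the observed 1-36 h design is unsafe, while
    clamping is conservative.
    """

    def __init__(self, ppoly: PPoly, t_min: float, t_max: float, kind: str = "spline"):
        self._pp = ppoly
        self.t_min = float(t_min)
        self.t_max = float(t_max)
        self.kind = kind

    def __call__(self, t) -> np.ndarray | float:
        arr = np.clip(np.asarray(t, dtype=float), self.t_min, self.t_max)
        out = self._pp(arr)
        return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "t_min": self.t_min,
            "t_max": self.t_max,
            "breakpoints": self._pp.x.tolist(),
            "coefficients": self._pp.c.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DriftFunction":
        pp = PPoly(np.asarray(d["coefficients"], dtype=float),
                   np.asarray(d["breakpoints"], dtype=float))
        return cls(pp, d["t_min"], d["t_max"], d["kind"])


@dataclass
class DriftCluster:
    cluster_id: int
    member_features: list[str]
    #: mean over member features' mean fold-change profiles, indexed by time
    cluster_profile: pd.Series
    drift_fn: DriftFunction

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "member_features": list(self.member_features),
            "profile_times": [float(t) for t in self.cluster_profile.index],
            "profile_values": [float(v) for v in self.cluster_profile.to_numpy()],
            "drift_fn": self.drift_fn.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DriftCluster":
        profile = pd.Series(d["profile_values"], index=d["profile_times"])
        return cls(
            cluster_id=int(d["cluster_id"]),
            member_features=[str(f) for f in d["member_features"]],
            cluster_profile=profile,
            drift_fn=DriftFunction.from_dict(d["drift_fn"]),
        )


@dataclass
class DriftModel:
    """Per-temperature collection of drift clusters and their drift functions.

    Every input feature appears exactly once: either as a member of one
    cluster or in ``excluded_features`` with a reason (``irreproducible`` for
    non-flat features with inconsistent between-subject kinetics,
    ``unassigned`` for features that could not be profiled, e.g. a zero
    intensity at the reference time).
    """

    temperature_c: float
    t_ref: float
    time_points: list[float]
    clusters: list[DriftCluster]
    excluded_features: list[tuple[str, str]]
    config: dict

    @property
    def feature_ids(self) -> list[str]:
        out = [f for c in self.clusters for f in c.member_features]
        out.extend(f for f, _ in self.excluded_features)
        return out

    def cluster_of(self) -> pd.Series:
        """Feature id -> cluster id (excluded features map to -1)."""
        mapping = {}
        for c in self.clusters:
            for f in c.member_features:
                mapping[f] = c.cluster_id
        for f, _ in self.excluded_features:
            mapping[f] = -1
        return pd.Series(mapping, name="cluster_id")

    def to_dict(self) -> dict:
        return {
            "temperature_c": float(self.temperature_c),
            "t_ref": float(self.t_ref),
            "time_points": [float(t) for t in self.time_points],
            "clusters": [c.to_dict() for c in self.clusters],
            "excluded_features": [[f, r] for f, r in self.excluded_features],
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DriftModel":
        return cls(
            temperature_c=float(d["temperature_c"]),
            t_ref=float(d["t_ref"]),
            time_points=[float(t) for t in d["time_points"]],
            clusters=[DriftCluster.from_dict(c) for c in d["clusters"]],
            excluded_features=[(str(f), str(r)) for f, r in d["excluded_features"]],
            config=dict(d["config"]),
        )


# -- stage 1: fold-change profiles -------------------------------------------

def compute_profiles(
    table: FeatureTable,
    meta: pd.DataFrame,
    t_ref: float = 1.0,
) -> tuple[list[DriftProfile], list[tuple[str, str]]]:
    """Per-subject fold-change profiles relative to the t_ref sample.

    For subject ``s`` and feature ``f`` the fold-change at time ``t`` is
    ``x_f(s, t) / x_f(s, t_ref)``; the mean profile averages fold-changes
    over subjects.  Reproducibility is the median of pairwise Pearson
    correlations between subjects' log fold-change profiles (defined as 0
    when a profile has zero variance, i.e. is flat).

    Returns the profiles plus a list of ``(feature_id, reason)`` for features
    that could not be profiled (zero intensity at the reference time).
    Requires a single temperature in ``meta`` and a t_ref sample per subject.
    """
    temps = meta["temperature_c"].unique()
    if len(temps) != 1:
        raise DriftModelError(
            f"single temperature required, got {sorted(temps)}"
        )
    times = np.sort(meta["time_h"].unique())
    if not np.any(np.isclose(times, t_ref)):
        raise DriftModelError(f"no samples at reference time {t_ref} h")

    subjects = sorted(meta["subject_id"].unique())
    # sample id per (subject, time)
    sample_at: dict[tuple[str, float], str] = {}
    for _, row in meta.iterrows():
        key = (row["subject_id"], float(row["time_h"]))
        if key in sample_at:
            raise DriftModelError(
                f"duplicate sample for subject {key[0]!r} at {key[1]} h"
            )
        sample_at[key] = row["sample_id"]
    for s in subjects:
        if not any(np.isclose(t, t_ref) for (subj, t) in sample_at if subj == s):
            raise DriftModelError(f"subject {s!r} has no sample at t_ref={t_ref} h")

    # subjects x times x features intensity cube, aligned on the table
    order = [sample_at[(s, t)] for s in subjects for t in times if (s, t) in sample_at]
    if len(order) != len(subjects) * len(times):
        raise DriftModelError("incomplete subject x time design")
    cube = table.subset(samples=order).values.reshape(
        len(subjects), len(times), table.n_features
    )
    ref_idx = int(np.argmin(np.abs(times - t_ref)))
    ref = cube[:, ref_idx, :]  # subjects x features

    profiles: list[DriftProfile] = []
    excluded: list[tuple[str, str]] = []
    for j, fid in enumerate(table.feature_ids):
        if (ref[:, j] <= 0).any() or (cube[:, :, j] <= 0).any():
            excluded.append((fid, "unassigned"))
            continue
        fc = cube[:, :, j] / ref[:, j][:, None]  # subjects x times
        per_subject = pd.DataFrame(fc, index=subjects, columns=times)
        mean_profile = pd.Series(fc.mean(axis=0), index=times)
        repro = _median_pairwise_corr(np.log(fc))
        profiles.append(
            DriftProfile(
                feature_id=fid,
                per_subject_profile=per_subject,
                mean_profile=mean_profile,
                reproducibility=repro,
            )
        )
    return profiles, excluded


def _median_pairwise_corr(log_fc: np.ndarray) -> float:
    """Median pairwise Pearson correlation between subject rows.

    Rows with zero variance (flat profiles) have undefined correlations;
    pairs involving them contribute 0 ("no evidence of shared kinetics").
    """
    n = log_fc.shape[0]
    if n < 2:
        return 0.0
    sd = log_fc.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(log_fc)
    vals = []
    for a in range(n):
        for b in range(a + 1, n):
            if sd[a] == 0 or sd[b] == 0:
                vals.append(0.0)
            else:
                vals.append(float(corr[a, b]))
    return float(np.median(vals))


# -- stage 2: irreproducibility filter ---------------------------------------

def filter_irreproducible(
    profiles: Sequence[DriftProfile],
    threshold: float = 0.5,
    flat_tol: float = 0.05,
) -> tuple[list[DriftProfile], list[tuple[str, str]]]:
    """Split profiles into reproducible (kept) and irreproducible (excluded).

    A feature is excluded iff its reproducibility falls below ``threshold``
    AND its mean profile departs from flat by more than ``flat_tol`` (max
    absolute log fold-change) at some time point.  Flat-but-noisy features
    are kept: they behave as stable and carry no drift signal to disagree on.
    """
    kept: list[DriftProfile] = []
    excluded: list[tuple[str, str]] = []
    for p in profiles:
        departure = float(np.max(np.abs(np.log(p.mean_profile.to_numpy()))))
        if p.reproducibility < threshold and departure > flat_tol:
            excluded.append((p.feature_id, "irreproducible"))
        else:
            kept.append(p)
    return kept, excluded


# -- stage 3: clustering ------------------------------------------------------

def cluster_profiles(
    kept: Sequence[DriftProfile],
    k_range: tuple[int, int] = (2, 30),
) -> list[tuple[int, list[str]]]:
    """Group mean drift profiles by hierarchical agglomerative clustering.

    Average linkage on Euclidean distances between log-transformed mean
    profiles; the number of clusters is selected within ``k_range`` by
    maximum mean silhouette width (ties toward the smallest k, for
    parsimony).  Degenerate inputs where all profiles coincide collapse to a
    single cluster.
    """
    if len(kept) < 2:
        raise DriftModelError(f"need >= 2 profiles to cluster, got {len(kept)}")
    lo, hi = int(k_range[0]), int(k_range[1])
    if lo < 1 or hi < lo:
        raise DriftModelError(f"invalid k_range {k_range}")
    if len(kept) < lo:
        raise DriftModelError(
            f"fewer profiles ({len(kept)}) than min cluster count ({lo})"
        )

    X = np.vstack([np.log(p.mean_profile.to_numpy()) for p in kept])
    fids = [p.feature_id for p in kept]
    if np.allclose(X, X[0], atol=1e-12):
        return [(1, list(fids))]

    Z = linkage(X, method="average", metric="euclidean")
    best_k, best_score = None, -np.inf
    for k in range(max(lo, 2), min(hi, len(kept) - 1) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(X, labels, metric="euclidean")
        if score > best_score + 1e-12:  # strict improvement: ties keep smaller k
            best_k, best_score = k, score
    if best_k is None:
        return [(1, list(fids))]
    labels = fcluster(Z, t=best_k, criterion="maxclust")
    out: list[tuple[int, list[str]]] = []
    for new_id, lab in enumerate(np.unique(labels), start=1):
        members = [fids[i] for i in np.flatnonzero(labels == lab)]
        out.append((new_id, members))
    return out


# -- stage 4: spline fitting ---------------------------------------------------

def fit_drift_fn(
    cluster_profile: Sequence[float] | pd.Series,
    time_points: Sequence[float] | None = None,
    t_ref: float = 1.0,
) -> DriftFunction:
    """Fit an anchored natural cubic spline drift function to a cluster mean.

    Interpolating natural cubic spline through the cluster-mean fold-changes
    when there are at most 5 time points (the 1/3/8/24/36 h design), a
    generalized-cross-validation smoothing spline otherwise.  The fitted
    curve is re-anchored by dividing by its value at ``t_ref`` so that
    ``g_c(t_ref) = 1`` exactly; if the anchored curve dips to a non-positive
    value anywhere on a dense grid it is replaced by a monotone-safe
    piecewise-linear interpolant of the anchored knot values (drift factors
    must stay positive for multiplicative correction).
    """
    if isinstance(cluster_profile, pd.Series):
        if time_points is None:
            time_points = [float(t) for t in cluster_profile.index]
        values = cluster_profile.to_numpy(dtype=float)
    else:
        values = np.asarray(cluster_profile, dtype=float)
    if time_points is None:
        raise DriftModelError("time_points required")
    t = np.asarray(time_points, dtype=float)
    if t.ndim != 1 or t.shape != values.shape:
        raise DriftModelError("time_points and profile lengths differ")
    if len(np.unique(t)) != len(t) or np.any(np.diff(t) <= 0):
        raise DriftModelError("time points must be strictly increasing and distinct")
    if len(t) < 4:
        raise DriftModelError(f"insufficient time points for spline fit ({len(t)} < 4)")
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise DriftModelError("cluster profile values must be positive and finite")
    if not (t[0] <= t_ref <= t[-1]):
        raise DriftModelError(f"t_ref={t_ref} outside observed time range")

    if len(t) <= 5:
        pp: PPoly = CubicSpline(t, values, bc_type="natural")
    else:
        pp = make_smoothing_spline(t, values)  # lam=None -> GCV
    anchor = float(pp(t_ref))
    if anchor <= 0:
        return _linear_fallback(t, values, t_ref)
    pp = PPoly(pp.c / anchor, pp.x)
    fn = DriftFunction(pp, t[0], t[-1], kind="spline")
    grid = np.linspace(t[0], t[-1], 512)
    if np.min(fn(grid)) <= 0:
        warnings.warn(
            "anchored drift spline non-positive on time range; "
            "falling back to piecewise-linear drift function",
            stacklevel=2,
        )
        return _linear_fallback(t, values, t_ref)
    return fn


def _linear_fallback(t: np.ndarray, values: np.ndarray, t_ref: float) -> DriftFunction:
    anchored = values / np.interp(t_ref, t, values)
    # degree-1 PPoly through the anchored knot values
    slopes = np.diff(anchored) / np.diff(t)
    c = np.vstack([slopes, anchored[:-1]])
    return DriftFunction(PPoly(c, t), t[0], t[-1], kind="linear")


# -- stage 5: composition -----------------------------------------------------

def fit_drift_model(
    table: FeatureTable,
    meta: pd.DataFrame,
    config: DriftConfig | None = None,
) -> DriftModel:
    """Fit the full per-temperature drift model.

    Composition of profile computation, irreproducibility filtering,
    profile clustering and per-cluster anchored spline fitting, with full
    feature accounting: every feature of ``table`` lands in exactly one
    cluster or in the excluded list.
    """
    config = config or DriftConfig()
    if len(np.unique(meta["time_h"])) < 4:
        raise DriftModelError(
            "insufficient time points: drift modeling needs >= 4 distinct times"
        )
    profiles, unprofiled = compute_profiles(table, meta, t_ref=config.t_ref)
    kept, irreproducible = filter_irreproducible(
        profiles, threshold=config.repro_threshold, flat_tol=config.flat_tol
    )
    assignments = cluster_profiles(kept, k_range=config.k_range)

    by_id = {p.feature_id: p for p in kept}
    times = np.sort(meta["time_h"].unique())
    clusters: list[DriftCluster] = []
    unassigned: list[tuple[str, str]] = []
    for cid, members in assignments:
        prof = np.vstack([by_id[f].mean_profile.to_numpy() for f in members]).mean(axis=0)
        cluster_profile = pd.Series(prof, index=times)
        try:
            fn = fit_drift_fn(cluster_profile, t_ref=config.t_ref)
        except DriftModelError:
            unassigned.extend((f, "unassigned") for f in members)
            continue
        clusters.append(
            DriftCluster(
                cluster_id=cid,
                member_features=list(members),
                cluster_profile=cluster_profile,
                drift_fn=fn,
            )
        )
    excluded = unprofiled + irreproducible + unassigned
    model = DriftModel(
        temperature_c=float(meta["temperature_c"].iloc[0]),
        t_ref=float(config.t_ref),
        time_points=[float(t) for t in times],
        clusters=clusters,
        excluded_features=excluded,
        config=config.to_dict(),
    )
    n_accounted = sum(len(c.member_features) for c in model.clusters) + len(excluded)
    assert n_accounted == table.n_features, "feature accounting violated"
    return model
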