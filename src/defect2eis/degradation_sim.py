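"""Synthetic detector-output generation of controlled accuracy.

Starting from a known true defect set, a degraded "detection result" is built
in three steps:

1. every defect's coordinates are jittered by independent Gaussian draws of
   standard deviation ``s`` (4 nm by default), emulating imperfect box
   localisation;
2. ``n_remove`` defects are deleted -- each removal target is the surviving
   defect nearest to a fresh sample from a kernel density estimate (KDE) of
   the true coordinates, so misses concentrate where defects concentrate
   (false negatives);
3. ``n_add`` new defects are inserted at KDE samples (false positives).

Because both removals and additions follow the KDE of the true pattern, the
degree of clustering of the degraded set stays close to that of the truth.

``case_grid`` enumerates the (n_remove, n_add) study design: both counts step
from 0 in increments of round(0.03 N) up to (but excluding) floor(N/2), and
the full Cartesian product is generated.  For N = 172 this yields 18 x 18 =
324 cases; for N = 158 and N = 97 it yields 16 x 16 = 256.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator

import numpy as np
from scipy.special import logsumexp

from .defect_sets import Defect, DefectSet, voronoi_sigma
from .detection_eval import AccuracyMetrics, evaluate
from .exceptions import ParameterError

DEFAULT_JITTER_S_NM = 4.0
DEFAULT_KDE_BANDWIDTH_NM = 400.0


@dataclasses.dataclass(frozen=True)
class DegradationParams:
    """Knobs of one degradation case.

    ``s`` and ``bandwidth`` are in nanometers.  ``seed`` feeds a dedicated
    :class:`numpy.random.Generator`, so every case is reproducible.
    """

    s: float = DEFAULT_JITTER_S_NM
    bandwidth: float = DEFAULT_KDE_BANDWIDTH_NM
    n_remove: int = 0
    n_add: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ParameterError(f"jitter s must be >= 0, got {self.s}")
        if self.bandwidth <= 0:
            raise ParameterError(f"bandwidth must be > 0, got {self.bandwidth}")
        if self.n_remove < 0 or self.n_add < 0:
            raise ParameterError("n_remove and n_add must be non-negative")


class KDEModel:
    """Isotropic Gaussian-mixture density over observed defect centers.

    One component per defect, common bandwidth (the kernel standard deviation,
    in nm).  Samples are rejection-resampled into the field rectangle.
    """

    def __init__(self, centers: np.ndarray, bandwidth: float, field_width: float, field_height: float) -> None:
        if bandwidth <= 0:
            raise ParameterError(f"bandwidth must be > 0, got {bandwidth}")
        centers = np.asarray(centers, dtype=float).reshape(-1, 2)
        if len(centers) < 1:
            raise ParameterError("KDE requires at least one kernel center")
        self.centers = centers
        self.bandwidth = float(bandwidth)
        self.field_width = float(field_width)
        self.field_height = float(field_height)

    def logpdf(self, points: np.ndarray) -> np.ndarray:
        """Log density of the (unbounded) mixture at the given (M, 2) points."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        d2 = ((pts[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        log_kernels = -d2 / (2.0 * self.bandwidth**2) - np.log(
            2.0 * np.pi * self.bandwidth**2 * len(self.centers)
        )
        return logsumexp(log_kernels, axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` points, rejection-resampling any that fall off the field."""
        out = np.empty((n, 2))
        filled = 0
        while filled < n:
            need = n - filled
            # over-draw so wide-bandwidth kernels (high rejection rates) stay fast
            batch = max(need, 4096)
            idx = rng.integers(0, len(self.centers), size=batch)
            pts = self.centers[idx] + rng.normal(0.0, self.bandwidth, size=(batch, 2))
            ok = (
                (pts[:, 0] >= 0.0)
                & (pts[:, 0] <= self.field_width)
                & (pts[:, 1] >= 0.0)
                & (pts[:, 1] <= self.field_height)
            )
            pts = pts[ok][:need]
            out[filled : filled + len(pts)] = pts
            filled += len(pts)
        return out


def fit_kde(true_set: DefectSet, bandwidth: float = DEFAULT_KDE_BANDWIDTH_NM) -> KDEModel:
    """Fit the Gaussian KDE of the true defect coordinates."""
    if len(true_set) < 1:
        raise ParameterError("cannot fit a KDE to an empty defect set")
    return KDEModel(
        true_set.coordinates, bandwidth, true_set.field_width, true_set.field_height
    )


def degrade(
    true_set: DefectSet,
    params: DegradationParams,
    kde: KDEModel | None = None,
) -> DefectSet:
    """Produce one degraded defect set (jitter, KDE-guided removals, additions).

    The output has exactly ``N - n_remove + n_add`` defects.  Jittered
    coordinates are clipped to the field rectangle so the result remains a
    valid :class:`DefectSet`.
    """
    n = len(true_set)
    if params.n_remove > n:
        raise ParameterError(f"n_remove={params.n_remove} exceeds N={n}")
    rng = np.random.default_rng(params.seed)
    if kde is None:
        kde = fit_kde(true_set, params.bandwidth)
    w, h = true_set.field_width, true_set.field_height

    xy = true_set.coordinates.copy()
    if n > 0 and params.s > 0:
        xy += rng.normal(0.0, params.s, size=xy.shape)
        np.clip(xy[:, 0], 0.0, w, out=xy[:, 0])
        np.clip(xy[:, 1], 0.0, h, out=xy[:, 1])

    alive = np.ones(n, dtype=bool)
    for target in kde.sample(params.n_remove, rng) if params.n_remove else ():
        live_idx = np.flatnonzero(alive)
        d2 = ((xy[live_idx] - target) ** 2).sum(axis=1)
        alive[live_idx[int(np.argmin(d2))]] = False

    added = kde.sample(params.n_add, rng) if params.n_add else np.empty((0, 2))
    r_box = true_set.defects[0].r_box if n else 25.0
    coords = np.vstack([xy[alive], added])
    return DefectSet.from_coordinates(
        coords, w, h, r_box=r_box,
        label=f"{true_set.label}/degraded(s={params.s},rm={params.n_remove},add={params.n_add})",
    )


def case_grid(n: int) -> list[tuple[int, int]]:
    """Enumerate (n_remove, n_add) cases for a true set of size ``n``.

    The step is round(0.03 n); both counts run 0, step, 2*step, ... strictly
    below floor(n/2), and the full Cartesian product is returned in row-major
    order (n_remove outer).
    """
    if n < 2:
        raise ParameterError(f"need N >= 2 to build a case grid, got {n}")
    step = round(0.03 * n)
    if step == 0:
        raise ParameterError(
            f"N={n} gives a zero step (3% of N rounds to 0); supply cases explicitly"
        )
    values = list(range(0, n // 2, step))
    return [(r, a) for r in values for a in values]


@dataclasses.dataclass(frozen=True)
class DegradationCase:
    """One scored synthetic detection case."""

    params: DegradationParams
    defect_set: DefectSet
    metrics: AccuracyMetrics
    sigma: float


def generate_batch(
    true_set: DefectSet,
    seed: int,
    s: float = DEFAULT_JITTER_S_NM,
    bandwidth: float = DEFAULT_KDE_BANDWIDTH_NM,
    cases: list[tuple[int, int]] | None = None,
    iou_threshold: float = 0.5,
) -> Iterator[DegradationCase]:
    """Yield one scored degraded set per (n_remove, n_add) case.

    Cases default to :func:`case_grid` of the true set size.  Each case gets a
    child seed spawned deterministically from ``seed``, so the whole batch is
    reproducible.  Every yielded case carries its detection metrics against
    the true set and its Voronoi clustering sigma.
    """
    if cases is None:
        cases = case_grid(len(true_set))
    kde = fit_kde(true_set, bandwidth)
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.generate_state(len(cases)) % (2**31)
    for (n_remove, n_add), child in zip(cases, child_seeds):
        params = DegradationParams(
            s=s, bandwidth=bandwidth, n_remove=n_remove, n_add=n_add, seed=int(child)
        )
        degraded = degrade(true_set, params, kde=kde)
        _, metrics = evaluate(true_set, degraded, iou_threshold)
        sigma = voronoi_sigma(degraded) if len(degraded) >= 3 else float("nan")
        yield DegradationCase(params, degraded, metrics, sigma)
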