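"""Decay-curve featurization.

Each curve is collapsed to seven scalars: five statistical descriptors of
the photon-count array (mean, standard deviation, skewness, maximum, and
the time at which the maximum occurs) and two parameters of a
single-exponential-plus-offset fit of the decaying tail,

    f(t) = a * exp(-b * t) + c,

of which the decay rate ``b`` (``fit_rate``, ns⁻¹ — the reciprocal of an
effective fluorescence lifetime) and the constant term ``c``
(``fit_const``) are kept; the amplitude ``a`` duplicates scale
information already carried by the mean and the maximum.  Optional
interaction features (products of every unordered pair of base features)
let linear models capture simple nonlinearities.

Moment conventions: population divisor ``n`` for the standard deviation
and the biased Fisher–Pearson skewness g1 = m3 / m2^(3/2).  These are the
defaults of the common scientific toolkits; the choice matters only in
the last digits for 1643-point curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dataset import DecayDataset, DecayRecord, dosage

logger = logging.getLogger(__name__)

#: Fixed base-feature column order.
BASE_FEATURES = (
    "counts_max",
    "counts_tix",
    "counts_avg",
    "counts_std",
    "counts_skew",
    "fit_rate",
    "fit_const",
)

TARGET_CHOICES = ("exposure", "concentration", "dosage")


class TailTooShortError(ValueError):
    """The sub-threshold decay tail has too few samples to fit."""


class FitError(RuntimeError):
    """The tail fit failed to converge (strict mode)."""


@dataclass(frozen=True)
class TailFit:
    """Result of the exponential-plus-offset tail fit."""

    a: float
    b: float
    c: float
    converged: bool
    rss: float
    n_points: int


@dataclass
class FeatureTable:
    """Named feature matrix with an optional regression target."""

    column_names: list[str]
    values: np.ndarray
    target: np.ndarray | None = None
    target_name: str = ""

    def __post_init__(self) -> None:
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("duplicate column names")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ValueError("values shape does not match column_names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)
            if len(self.target) != len(self.values):
                raise ValueError("target length does not match row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        if self.target is not None:
            df[self.target_name or "target"] = self.target
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, target_name: str | None = None) -> "FeatureTable":
        df = pd.read_csv(path)
        target = None
        if target_name is not None and target_name in df.columns:
            target = df.pop(target_name).to_numpy()
        return cls(list(df.columns), df.to_numpy(), target=target,
                   target_name=target_name or "")


def summary_stats(record: DecayRecord) -> dict[str, float]:
    """The five statistical descriptors of one photon-count array.

    Zero-variance curves get std = 0 and skew defined as 0 (logged guard);
    ties on the maximum resolve to its first occurrence.
    """
    c = np.asarray(record.counts, dtype=float)
    if len(c) < 3:
        raise ValueError("need at least 3 samples for moment features")
    mean = float(c.mean())
    if np.ptp(c) == 0:  # exactly constant: avoid rounding noise in the moments
        mean, m2 = float(c[0]), 0.0
    else:
        m2 = float(np.mean((c - mean) ** 2))
    std = float(np.sqrt(m2))
    if m2**1.5 == 0.0:  # zero variance, or variance underflowing the cube root
        logger.info("sample %s: zero-variance counts, skew set to 0", record.sample_id)
        skew = 0.0
    else:
        m3 = float(np.mean((c - mean) ** 3))
        skew = m3 / m2**1.5
    imax = int(np.argmax(c))
    return {
        "counts_max": float(c[imax]),
        "counts_tix": float(record.time_ns[imax]),
        "counts_avg": mean,
        "counts_std": std,
        "counts_skew": skew,
    }


def select_tail(record: DecayRecord, threshold_fraction: float = 0.95) -> slice:
    """Index range of the decaying tail below ``threshold_fraction`` of the peak.

    The tail starts at the first sample strictly after the (first) maximum
    whose count drops below ``threshold_fraction * max`` and runs to the end
    of the array.
    """
    c = np.asarray(record.counts, dtype=float)
    cmax = c.max()
    if cmax <= 0:
        raise ValueError(f"sample {record.sample_id}: all-zero counts, no tail")
    imax = int(np.argmax(c))
    below = np.nonzero(c[imax + 1 :] < threshold_fraction * cmax)[0]
    if len(below) == 0:
        raise TailTooShortError(f"sample {record.sample_id}: no sub-threshold tail")
    start = imax + 1 + int(below[0])
    if len(c) - start < 10:
        raise TailTooShortError(
            f"sample {record.sample_id}: tail has {len(c) - start} samples (< 10)"
        )
    return slice(start, len(c))


def _exp_model(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    a, b, c = params
    return a * np.exp(-b * t) + c


def tail_fit(
    time_tail: Sequence[float],
    counts_tail: Sequence[float],
    init: tuple[float, float, float] | None = None,
) -> TailFit:
    """Least-squares fit of ``a * exp(-b t) + c`` to the decay tail.

    The decay rate is constrained non-negative.  When ``init`` is not
    given, the start point is built from the data: ``c0`` is the mean of
    the last 5% of tail samples, ``a0`` the first tail value above that
    offset, and ``b0`` the slope of a log-linear regression of the
    offset-subtracted counts.  Deterministic for fixed inputs.
    """
    t = np.asarray(time_tail, dtype=float)
    y = np.asarray(counts_tail, dtype=float)
    if len(t) < 10:
        raise TailTooShortError(f"tail has {len(t)} samples (< 10)")
    if np.any(np.diff(t) <= 0):
        raise ValueError("tail times must be strictly increasing")
    if np.ptp(y) == 0:  # constant tail: exponential model is degenerate
        return TailFit(a=0.0, b=0.0, c=float(y[0]), converged=False,
                       rss=0.0, n_points=len(t))

    if init is None:
        n_off = max(1, int(round(0.05 * len(y))))
        c0 = float(np.mean(y[-n_off:]))
        a0 = max(float(y[0] - c0), 1e-6)
        resid = np.maximum(y - c0, 1e-12)
        slope = np.polyfit(t, np.log(resid), 1)[0]
        b0 = max(-float(slope), 1e-6)
        init = (a0, b0, c0)

    a0, b0, c0 = init
    lo = np.array([-np.inf, 0.0, -np.inf])
    hi = np.array([np.inf, np.inf, np.inf])
    x0 = np.clip(np.array([a0, b0, c0], dtype=float), lo, hi)
    sol = least_squares(
        lambda p: _exp_model(p, t) - y,
        x0=x0,
        bounds=(lo, hi),
        method="trf",
        max_nfev=2000,
    )
    a, b, c = (float(v) for v in sol.x)
    rss = float(np.sum(sol.fun**2))
    # a ≈ 0 or b pinned at 0 means the model degenerated to a constant.
    degenerate = (abs(a) < 1e-10 * max(abs(c), 1.0)) or (b < 1e-12 and np.ptp(y) > 0)
    converged = bool(sol.success) and not degenerate
    return TailFit(a=a, b=b, c=c, converged=converged, rss=rss, n_points=len(t))


def fit_record_tail(
    record: DecayRecord, threshold_fraction: float = 0.95
) -> TailFit:
    """Select the tail of one record and fit the exponential model to it."""
    sl = select_tail(record, threshold_fraction)
    return tail_fit(record.time_ns[sl], record.counts[sl])


def interaction_names(base: Sequence[str] = BASE_FEATURES) -> list[str]:
    """Names of the pairwise interaction columns, ``"x*y"`` per unordered pair."""
    return [f"{x}*{y}" for x, y in combinations(base, 2)]


def build_feature_table(
    ds: DecayDataset,
    target_name: str = "dosage",
    include_interactions: bool = True,
    normalize_counts: bool = False,
    strict: bool = False,
) -> FeatureTable:
    """Featurize every record of a (length-conformed) dataset.

    Records whose tail fit fails are dropped with a logged count (or raise
    :class:`FitError` in strict mode).  ``normalize_counts`` divides each
    curve by its maximum before the statistical moments are taken (the fit
    features are always computed on raw counts).
    """
    if target_name not in TARGET_CHOICES:
        raise ValueError(f"target_name must be one of {TARGET_CHOICES}")
    rows: list[list[float]] = []
    targets: list[float] = []
    dropped = 0
    for r in ds:
        try:
            fit = fit_record_tail(r)
            if not fit.converged:
                raise FitError(f"sample {r.sample_id}: tail fit did not converge")
        except (TailTooShortError, FitError, ValueError) as exc:
            if strict:
                raise FitError(str(exc)) from exc
            dropped += 1
            continue
        rec = r
        if normalize_counts:
            from dataclasses import replace

            rec = replace(r, counts=r.counts / r.counts.max())
        stats = summary_stats(rec)
        row = [stats[k] for k in BASE_FEATURES[:5]] + [fit.b, fit.c]
        rows.append(row)
        if target_name == "exposure":
            targets.append(r.exposure_h)
        elif target_name == "concentration":
            targets.append(r.concentration_ugml)
        else:
            targets.append(dosage(r))
    if dropped:
        logger.warning("dropped %d records with failed tail fits", dropped)
    if not rows:
        raise ValueError("all records dropped: empty feature table")

    values = np.asarray(rows, dtype=float)
    names = list(BASE_FEATURES)
    if include_interactions:
        pairs = list(combinations(range(len(BASE_FEATURES)), 2))
        inter = np.column_stack([values[:, i] * values[:, j] for i, j in pairs])
        values = np.hstack([values, inter])
        names += interaction_names()
    return FeatureTable(names, values, target=np.asarray(targets), target_name=target_name)


@dataclass(frozen=True)
class Standardizer:
    """Per-column location/scale fitted on a training subset."""

    means: np.ndarray
    scales: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.means) / self.scales

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        return values * self.scales + self.means


def standardize(
    table: FeatureTable, fit_rows: Sequence[int] | None = None
) -> tuple[FeatureTable, Standardizer]:
    """Zero-mean/unit-std each column, with statistics from ``fit_rows`` only.

    Population standard deviation (divisor n).  A constant column among the
    fit rows is an error naming the column.
    """
    fit_rows = np.arange(table.n_rows) if fit_rows is None else np.asarray(fit_rows)
    if len(fit_rows) == 0:
        raise ValueError("fit_rows is empty")
    sub = table.values[fit_rows]
    means = sub.mean(axis=0)
    scales = sub.std(axis=0)
    bad = np.nonzero(scales == 0)[0]
    if len(bad):
        raise ValueError(f"constant column among fit rows: '{table.column_names[bad[0]]}'")
    std = Standardizer(means=means, scales=scales)
    out = FeatureTable(
        list(table.column_names),
        std.transform(table.values),
        target=None if table.target is None else table.target.copy(),
        target_name=table.target_name,
    )
    return out, std
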