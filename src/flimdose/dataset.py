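"""Decay-curve dataset handling.

A *record* is one cell's aggregated TCSPC fluorescence decay curve — the
photon counts of all pixels of a FLIM map summed per time bin — together
with the experimental labels: Cu(II) concentration (µg mL⁻¹), exposure
time (h) and a cell serial number.  Datasets are exchanged as a JSON file
holding one object per record with keys ``sample``, ``time``, ``counts``,
``date``, ``exposure``, ``concentration``, ``cell``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

#: Common curve length after trimming (points on the 0.008 ns grid).
DEFAULT_CURVE_LENGTH = 1643

_REQUIRED_KEYS = ("sample", "time", "counts", "date", "exposure", "concentration", "cell")


class SchemaError(ValueError):
    """A record in the JSON file is missing a required field."""


class ValidationError(ValueError):
    """A record violates a structural invariant (lengths, ordering, signs)."""


@dataclass(frozen=True)
class DecayRecord:
    """One aggregated decay curve plus its experimental labels.

    ``time_ns`` must be strictly increasing with uniform spacing; ``counts``
    are non-negative photon counts on the same grid.
    """

    sample_id: int
    time_ns: np.ndarray
    counts: np.ndarray
    date: str
    exposure_h: float
    concentration_ugml: float
    cell_id: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_ns", np.asarray(self.time_ns, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        self._validate()

    def _validate(self) -> None:
        t, c = self.time_ns, self.counts
        if t.ndim != 1 or c.ndim != 1 or len(t) != len(c):
            raise ValidationError(
                f"sample {self.sample_id}: time grid has {len(t)} points "
                f"but counts has {len(c)}"
            )
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValidationError(f"sample {self.sample_id}: time grid not strictly increasing")
            spread = (dt.max() - dt.min()) / dt.mean()
            if spread > 1e-6:
                raise ValidationError(
                    f"sample {self.sample_id}: non-uniform time grid (relative spread {spread:.2e})"
                )
        if np.any(c < 0):
            raise ValidationError(f"sample {self.sample_id}: negative photon counts")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def dt_ns(self) -> float:
        """Grid spacing in ns."""
        return float(self.time_ns[1] - self.time_ns[0])


@dataclass
class DecayDataset:
    """Ordered collection of :class:`DecayRecord` with unique sample ids."""

    records: list[DecayRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DecayRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> DecayRecord:
        return self.records[i]

    def label_table(self) -> pd.DataFrame:
        """Label summary: one row per record with sample id, labels and dosage."""
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "concentration": [r.concentration_ugml for r in self.records],
                "exposure": [r.exposure_h for r in self.records],
                "cell": [r.cell_id for r in self.records],
                "dosage": [dosage(r) for r in self.records],
            }
        )


def _record_from_obj(obj: dict, index: int) -> DecayRecord:
    for key in _REQUIRED_KEYS:
        if key not in obj:
            raise SchemaError(f"record {index}: missing required field '{key}'")
    return DecayRecord(
        sample_id=int(obj["sample"]),
        time_ns=np.asarray(obj["time"], dtype=float),
        counts=np.asarray(obj["counts"], dtype=float),
        date=str(obj["date"]),
        exposure_h=float(obj["exposure"]),
        concentration_ugml=float(obj["concentration"]),
        cell_id=int(obj["cell"]),
    )


def load_dataset(path: str | Path) -> DecayDataset:
    """Load a decay-curve dataset from its JSON file.

    Accepts either a bare JSON array of record objects or an object with a
    ``records`` array (and optional ``provenance`` string).
    """
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    provenance = ""
    if isinstance(payload, dict):
        provenance = str(payload.get("provenance", ""))
        payload = payload.get("records")
        if payload is None:
            raise SchemaError(f"{path}: top-level object has no 'records' array")
    records = [_record_from_obj(obj, i) for i, obj in enumerate(payload)]
    ds = DecayDataset(records, provenance=provenance or str(path))
    logger.info("loaded %d records from %s", len(ds), path)
    return ds


def write_dataset(ds: DecayDataset, path: str | Path) -> None:
    """Write the dataset in the same JSON dialect ``load_dataset`` reads.

    Integer fields round-trip bit-compatibly; counts are written as integers
    when they are integral.
    """
    out = []
    for r in ds.records:
        counts = r.counts
        if np.all(counts == np.round(counts)):
            counts_list = [int(c) for c in counts]
        else:
            counts_list = counts.tolist()
        out.append(
            {
                "sample": int(r.sample_id),
                "time": r.time_ns.tolist(),
                "counts": counts_list,
                "date": r.date,
                "exposure": r.exposure_h,
                "concentration": r.concentration_ugml,
                "cell": int(r.cell_id),
            }
        )
    with open(path, "w") as fh:
        json.dump(out, fh)


def conform_lengths(ds: DecayDataset, target_len: int = DEFAULT_CURVE_LENGTH) -> DecayDataset:
    """Trim every record to its first ``target_len`` points.

    Raw acquisitions carry a variable number of grid points; the decaying
    tail end carries negligible signal, so curves are conformed by prefix
    retention (never resampling).  Records shorter than ``target_len`` are
    an error.
    """
    short = [(r.sample_id, len(r)) for r in ds.records if len(r) < target_len]
    if short:
        sid, n = short[0]
        raise ValidationError(
            f"sample {sid} has {n} points, fewer than target length {target_len}"
        )
    trimmed = [
        replace(r, time_ns=r.time_ns[:target_len], counts=r.counts[:target_len])
        for r in ds.records
    ]
    return DecayDataset(trimmed, provenance=ds.provenance)


def filter_records(
    ds: DecayDataset,
    predicate: Callable[[int, float, float], bool],
) -> DecayDataset:
    """Keep records for which ``predicate(sample_id, concentration, exposure)``
    is true; order preserved, empty result permitted."""
    kept = [
        r
        for r in ds.records
        if predicate(r.sample_id, r.concentration_ugml, r.exposure_h)
    ]
    logger.info("filter kept %d of %d records", len(kept), len(ds))
    return DecayDataset(kept, provenance=ds.provenance)


def dosage(record: DecayRecord) -> float:
    """Cu(II) dosage: concentration × exposure time (µg mL⁻¹ h)."""
    return record.concentration_ugml * record.exposure_h


def _bin_target(targets: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize a continuous target into strata for stratified splitting.

    Targets with ≤ 10 distinct values are stratified on the values directly;
    otherwise quantile bins are used.
    """
    targets = np.asarray(targets, dtype=float)
    uniq = np.unique(targets)
    if len(uniq) <= 10:
        return np.searchsorted(uniq, targets)
    binned = pd.qcut(targets, q=n_bins, labels=False, duplicates="drop")
    return np.asarray(binned, dtype=int)


def stratified_split_indices(
    targets: Sequence[float],
    test_fraction: float = 0.2,
    seed: int = 1,
    n_bins: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split of ``range(len(targets))`` on the binned target.

    Returns sorted ``(train_idx, test_idx)``; the test set holds
    ``round(test_fraction * n)`` members.  Falls back to an unstratified
    split (with a warning) when some stratum has fewer than 2 members.
    """
    targets = np.asarray(targets, dtype=float)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(targets)
    strata = _bin_target(targets, n_bins)
    n_test = int(round(test_fraction * n))
    uniq, counts = np.unique(strata, return_counts=True)
    stratify = strata
    if counts.min() < 2 or n_test < len(uniq) or (n - n_test) < len(uniq):
        warnings.warn(
            "strata too small for the requested split; falling back to unstratified",
            stacklevel=2,
        )
        stratify = None
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, test_size=n_test, random_state=seed, stratify=stratify
    )
    return np.sort(train_idx), np.sort(test_idx)


def split_train_test(
    ds: DecayDataset,
    targets: Sequence[float],
    test_fraction: float = 0.2,
    seed: int = 1,
    n_bins: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split of a dataset's record indices.

    ``targets`` must align with the records; see
    :func:`stratified_split_indices` for the stratification rule.
    """
    if len(targets) != len(ds):
        raise ValueError(f"targets length {len(targets)} != record count {len(ds)}")
    return stratified_split_indices(targets, test_fraction, seed, n_bins)
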