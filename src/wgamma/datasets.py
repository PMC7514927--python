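"""Benchmark lifetime datasets, shipped as immutable in-package fixtures.

Five classical positive-valued samples used to benchmark lifetime
models: two sets of failure/running times of repairable systems (ties
at the 3.00 / 300 running-time cap are treated as complete
observations, matching the published analyses), component lifetimes,
waiting times between eruptions of the Kiama Blowhole, and monthly
Egyptian tax revenues.  Values are stored exactly as printed in their
sources, in printed order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Dataset", "load_dataset", "read_sample", "write_sample", "DATASET_NAMES"]


@dataclass(frozen=True)
class Dataset:
    """A named, immutable positive-real sample with provenance."""

    name: str
    values: tuple
    source: str

    @property
    def n(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(self.values, dtype=float)

    def __array__(self, dtype=None, copy=None):
        return np.array(self.values, dtype=dtype or float)


_RAW = {
    "units30": (
        (2.75, 0.13, 1.47, 0.23, 1.81, 0.30, 0.65, 0.10, 3.00, 1.73,
         1.06, 3.00, 3.00, 2.12, 3.00, 3.00, 3.00, 0.02, 2.61, 2.93,
         0.88, 2.47, 0.28, 1.43, 3.00, 0.23, 3.00, 0.80, 2.45, 2.66),
        "failure and running times of a large system with 30 units (Meeker & Escobar)",
    ),
    "components50": (
        (0.1, 0.2, 1.0, 1.0, 1.0, 1.0, 1.0, 2.0, 3.0, 6.0,
         7.0, 11.0, 12.0, 18.0, 18.0, 18.0, 18.0, 18.0, 21.0, 32.0,
         36.0, 40.0, 45.0, 46.0, 47.0, 50.0, 55.0, 60.0, 63.0, 63.0,
         67.0, 67.0, 67.0, 67.0, 72.0, 75.0, 79.0, 82.0, 82.0, 83.0,
         84.0, 84.0, 84.0, 85.0, 85.0, 85.0, 85.0, 85.0, 86.0, 86.0),
        "lifetimes of 50 components (Aarset)",
    ),
    "devices30": (
        (2.0, 10.0, 13.0, 23.0, 23.0, 28.0, 30.0, 65.0, 80.0, 88.0,
         106.0, 143.0, 147.0, 173.0, 181.0, 212.0, 245.0, 247.0, 261.0, 266.0,
         275.0, 293.0, 300.0, 300.0, 300.0, 300.0, 300.0, 300.0, 300.0, 300.0),
        "failure and running times of a sample of 30 devices (Meeker & Escobar)",
    ),
    "kiama": (
        (83.0, 51.0, 87.0, 60.0, 28.0, 95.0, 8.0, 27.0, 15.0, 10.0,
         18.0, 16.0, 29.0, 54.0, 91.0, 8.0, 17.0, 55.0, 10.0, 35.0,
         47.0, 77.0, 36.0, 17.0, 21.0, 36.0, 18.0, 40.0, 10.0, 7.0,
         34.0, 27.0, 28.0, 56.0, 8.0, 25.0, 68.0, 146.0, 89.0, 18.0,
         73.0, 69.0, 9.0, 37.0, 10.0, 82.0, 29.0, 8.0, 60.0, 61.0,
         61.0, 18.0, 169.0, 25.0, 8.0, 26.0, 11.0, 83.0, 11.0, 42.0,
         17.0, 14.0, 9.0, 12.0),
        "waiting times between 65 consecutive eruptions of the Kiama Blowhole "
        "(64 inter-event intervals)",
    ),
    "egypt_tax": (
        (5.9, 20.4, 14.9, 16.2, 17.2, 7.8, 6.1, 9.2, 10.2, 9.6,
         13.3, 8.5, 21.6, 18.5, 5.1, 6.7, 17.0, 8.6, 9.7, 39.2,
         35.7, 15.7, 9.7, 10.0, 4.1, 36.0, 8.5, 8.0, 9.2, 26.2,
         21.9, 16.7, 21.3, 35.4, 14.3, 8.5, 10.6, 19.1, 20.5, 7.1,
         7.7, 18.1, 16.5, 11.9, 7.0, 8.6, 12.5, 10.3, 11.2, 6.1,
         8.4, 11.0, 11.6, 11.9, 5.2, 6.8, 8.9, 7.1, 10.8),
        "monthly actual tax revenue in Egypt, Jan 2006 - Nov 2010 "
        "(1000 million Egyptian pounds)",
    ),
}

DATASET_NAMES = tuple(_RAW)


def load_dataset(name: str) -> Dataset:
    """Return a packaged benchmark sample by name.

    Valid names: units30, components50, devices30, kiama, egypt_tax.
    """
    try:
        values, source = _RAW[name]
    except KeyError:
        raise KeyError(
            f"unknown dataset {name!r}; valid names: {', '.join(DATASET_NAMES)}"
        ) from None
    return Dataset(name=name, values=values, source=source)


def read_sample(path, name: str | None = None) -> Dataset:
    """Read a single-column CSV of positive reals (optional header line).

    Row order is preserved; non-numeric or non-positive entries raise a
    ValueError naming the offending line.
    """
    values = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or not row[0].strip():
                continue
            cell = row[0].strip()
            try:
                v = float(cell)
            except ValueError:
                if lineno == 1 and not values:
                    continue  # single header line
                raise ValueError(f"{path}:{lineno}: non-numeric entry {cell!r}") from None
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive entry {cell!r}")
            values.append(v)
    if not values:
        raise ValueError(f"{path}: no numeric values found")
    return Dataset(name=name or str(path), values=tuple(values), source=str(path))


def write_sample(dataset: Dataset, path, header: str = "time") -> None:
    """Write a sample as a single-column CSV with a header line."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([header])
        for v in dataset.values:
            writer.writerow([repr(float(v))])
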