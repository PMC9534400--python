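"""Labeled crown-color point tables: reading, validation, and the
train/test partition.

Points are photo-interpreted pixels labeled with one of the four crown
color classes plus their raw RGB values and optional stratum metadata
(state, imagery year, ecoregion code, digitizer, NIR, coordinates).  The
partition rule follows the calibration workflow: within each stratum
(state x year by default), classes with at least ``min_class_n`` points
are split 90/10 into training/testing; smaller classes contribute all
points to training and none to testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .color_model import CrownClass

__all__ = ["read_points", "write_points", "split_train_test", "PointPartition"]

REQUIRED_COLUMNS = ("class", "r", "g", "b")
OPTIONAL_COLUMNS = ("nir", "state", "year", "ecocode", "digitizer", "lon", "lat")
VALID_LABELS = frozenset(c.label for c in
                         (CrownClass.GREEN, CrownClass.RED, CrownClass.GRAY,
                          CrownClass.SHADOW))


def _validate(df: pd.DataFrame, bits: int) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = df.copy()
    df["class"] = df["class"].astype(str).str.strip().str.lower()
    bad = df.index[~df["class"].isin(VALID_LABELS)]
    if len(bad):
        row = bad[0]
        raise ValueError(
            f"row {row}: invalid crown class label {df.loc[row, 'class']!r} "
            f"(expected one of {sorted(VALID_LABELS)})")
    top = 2 ** bits - 1
    for ch in ("r", "g", "b"):
        vals = pd.to_numeric(df[ch], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0) | (vals > top) | (vals % 1 != 0)]
        if len(bad):
            row = bad[0]
            raise ValueError(
                f"row {row}: channel {ch}={df.loc[row, ch]!r} not an integer "
                f"in [0, {top}]")
        df[ch] = vals.astype(np.int64)
    return df


def read_points(path, bits: int = 8) -> pd.DataFrame:
    """Read a labeled point table from CSV or GeoJSON.

    CSV schema: ``class,r,g,b[,nir,state,year,ecocode,digitizer,lon,lat]``.
    GeoJSON: Point features carrying the same fields as properties (lon/lat
    taken from the geometry).  Returns a validated DataFrame; raises
    ``ValueError`` naming the first offending row otherwise.
    """
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        with open(path) as fh:
            gj = json.load(fh)
        rows = []
        for i, feat in enumerate(gj.get("features", [])):
            props = dict(feat.get("properties") or {})
            geom = feat.get("geometry") or {}
            if geom.get("type") == "Point":
                props.setdefault("lon", geom["coordinates"][0])
                props.setdefault("lat", geom["coordinates"][1])
            rows.append(props)
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    return _validate(df, bits)


def write_points(df: pd.DataFrame, path) -> None:
    """Write a point table to CSV."""
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def class_counts(df: pd.DataFrame) -> dict:
    return df["class"].value_counts().to_dict()


@dataclass
class PointPartition:
    """A train/test split of a point table, with its provenance."""

    train: pd.DataFrame
    test: pd.DataFrame
    fraction: float
    seed: int
    min_class_n: int
    stratum_cols: tuple = ()
    counts: dict = field(default_factory=dict)

    @property
    def manifest(self) -> dict:
        return {
            "fraction": self.fraction,
            "seed": self.seed,
            "min_class_n": self.min_class_n,
            "stratum_cols": list(self.stratum_cols),
            "n_train": int(len(self.train)),
            "n_test": int(len(self.test)),
            "counts": self.counts,
        }

    def write(self, directory, stem: str = "points") -> None:
        """Write the partition as two CSVs plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_points(self.train, directory / f"{stem}_train.csv")
        write_points(self.test, directory / f"{stem}_test.csv")
        with open(directory / f"{stem}_manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)


def split_train_test(points: pd.DataFrame,
                     fraction: float = 0.9,
                     min_class_n: int = 50,
                     seed: int = 0,
                     stratum_cols=None) -> PointPartition:
    """Partition points into training and testing sets.

    Per class within each stratum: if the class has at least
    ``min_class_n`` points, a random ``1 - fraction`` share (rounded, at
    least one point) is withheld for testing; otherwise every point goes
    to training.  The split is reproducible under ``seed`` and never mixes
    strata.

    ``stratum_cols`` defaults to ``("state", "year")`` when both columns
    are present, else no stratification.
    """
    if len(points) == 0:
        raise ValueError("empty point table")
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if stratum_cols is None:
        stratum_cols = tuple(c for c in ("state", "year") if c in points.columns)
    else:
        stratum_cols = tuple(stratum_cols)

    rng = np.random.default_rng(seed)
    keys = ["class", *stratum_cols]
    test_idx: list = []
    counts: dict = {}
    # sorted group order keeps the draw sequence deterministic
    for key, group in points.groupby(keys, sort=True, dropna=False):
        n = len(group)
        label = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        if n >= min_class_n:
            n_test = max(1, round((1.0 - fraction) * n))
            chosen = rng.choice(group.index.to_numpy(), size=n_test, replace=False)
            test_idx.extend(chosen.tolist())
        else:
            n_test = 0
        counts[label] = {"total": n, "test": n_test, "train": n - n_test}

    test_mask = points.index.isin(test_idx)
    return PointPartition(
        train=points.loc[~test_mask].copy(),
        test=points.loc[test_mask].copy(),
        fraction=fraction, seed=seed, min_class_n=min_class_n,
        stratum_cols=stratum_cols, counts=counts)
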