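"""Trained parameter models: spline interpolation over per-MAF knot tables.

Three bundled models — ``clean``, ``contaminated`` and ``combined`` — carry
five tuned values (cor, ii, pp, np, dp) at each of five training MAF grid
points (0.01 … 0.05).  A cubic interpolating spline (smoothing factor 0, so
the knot values are reproduced exactly) serves values at any MAF in between.
The spline is densified to 500 evenly spaced points (the original knot MAFs
retained in the grid) and refit, mirroring a store-and-reload round trip;
the refit changes evaluations by < 1e-6 anywhere on the training range.

Users can retrain and supply their own knot TSV (header
``maf cor ii pp np dp``) via :func:`load_knots`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import InterpolatedUnivariateSpline

from .scoring import ParameterSet

MODEL_NAMES = ("clean", "contaminated", "combined")
PARAM_NAMES = ("cor", "ii", "pp", "np", "dp")
_DENSE_POINTS = 500


@dataclass
class ParameterKnots:
    """A knot table: one row of tuned values per training MAF."""

    model_name: str
    table: pd.DataFrame  # columns: maf, cor, ii, pp, np, dp

    def __post_init__(self) -> None:
        missing = {"maf", *PARAM_NAMES} - set(self.table.columns)
        if missing:
            raise ValueError(f"knot table lacks columns: {sorted(missing)}")
        mafs = self.table["maf"].to_numpy()
        if len(mafs) < 4:
            raise ValueError("need at least 4 knots for a cubic spline")
        if not np.all(np.diff(mafs) > 0):
            raise ValueError("knot MAF values must be strictly increasing")
        if (self.table[list(PARAM_NAMES)].to_numpy() <= 0).any():
            raise ValueError("all knot parameter values must be > 0")

    @property
    def maf_range(self) -> tuple[float, float]:
        mafs = self.table["maf"].to_numpy()
        return float(mafs[0]), float(mafs[-1])


def _bundled_path(name: str):
    return resources.files("strainvar.data").joinpath(f"{name}.tsv")


def load_knots(source: str | Path) -> ParameterKnots:
    """Load a knot table: a bundled model name or a path to a knot TSV."""
    if isinstance(source, str) and source in MODEL_NAMES:
        with resources.as_file(_bundled_path(source)) as path:
            table = pd.read_csv(path, sep="\t")
        return ParameterKnots(source, table)
    path = Path(source)
    if path.exists():
        return ParameterKnots(path.stem, pd.read_csv(path, sep="\t"))
    raise ValueError(
        f"unknown parameter model {source!r}; valid names: {', '.join(MODEL_NAMES)} "
        "(or a path to a knot TSV)"
    )


def save_knots(knots: ParameterKnots, path: str | Path) -> None:
    knots.table.to_csv(path, sep="\t", index=False)


class ParameterModel:
    """Per-parameter spline evaluators fitted from a knot table."""

    def __init__(self, knots: ParameterKnots):
        self.knots = knots
        self.lo, self.hi = knots.maf_range
        mafs = knots.table["maf"].to_numpy(dtype=float)
        dense = np.union1d(np.linspace(self.lo, self.hi, _DENSE_POINTS), mafs)
        self._splines: dict[str, InterpolatedUnivariateSpline] = {}
        for name in PARAM_NAMES:
            vals = knots.table[name].to_numpy(dtype=float)
            first = InterpolatedUnivariateSpline(mafs, vals, k=3)
            # store/refit round trip: the dense grid keeps the knots so the
            # printed values survive exactly
            self._splines[name] = InterpolatedUnivariateSpline(
                dense, first(dense), k=3
            )

    def evaluate(self, maf: float, name: str) -> float:
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
        maf = self._clip(maf)
        return max(float(self._splines[name](maf)), 0.0)

    def _clip(self, maf: float) -> float:
        if maf < self.lo or maf > self.hi:
            clipped = min(max(maf, self.lo), self.hi)
            warnings.warn(
                f"MAF {maf} outside the trained range [{self.lo}, {self.hi}]; "
                f"clipped to {clipped} (no extrapolation)"
            )
            return clipped
        return maf

    def lookup(self, maf: float) -> ParameterSet:
        """Interpolated parameter set for *maf* (values floored at 0)."""
        eff = self._clip(maf)
        return ParameterSet(
            maf=maf, **{name: self.evaluate(eff, name) for name in PARAM_NAMES}
        )


def fit_model(knots: ParameterKnots) -> ParameterModel:
    return ParameterModel(knots)


_CACHE: dict[str, ParameterModel] = {}


def get_model(model_name: str = "combined") -> ParameterModel:
    if model_name not in _CACHE:
        _CACHE[model_name] = fit_model(load_knots(model_name))
    return _CACHE[model_name]


def lookup(maf: float, model_name: str = "combined") -> ParameterSet:
    """Parameter set for *maf* under a bundled model (default: combined)."""
    return get_model(model_name).lookup(maf)
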