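"""Apply a fitted land-use-regression model to receptors or a raster grid.

Prediction is the linear evaluation intercept + beta . x. Standard LUR
practice clamps each predictor to the range observed at the training sites
before evaluating (extrapolation outside the monitored conditions is not
trusted); negative predictions are floored at zero since concentrations are
non-negative. Both interventions are on by default and every affected cell
is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError
from .geo_predictors import PredictorMatrix, build_predictor_matrix
from .lur_model import LurModel
from .scene import CityScene


@dataclass
class PredictionGrid:
    """Predicted concentrations at receptors, optionally on a raster layout."""

    receptor_ids: list
    values: np.ndarray  # ug/m3 per receptor
    truncated: np.ndarray  # bool per receptor: any predictor was clamped
    floored: np.ndarray  # bool per receptor: prediction raised to 0
    model_id: str
    raster: dict | None = None  # {'x0','y0','cell','nrows','ncols'} when gridded

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "receptor_id": self.receptor_ids,
                "predicted_ugm3": self.values,
                "truncated": self.truncated,
                "floored": self.floored,
            }
        )

    def to_array(self) -> np.ndarray:
        if self.raster is None:
            raise ValueError("not a raster prediction")
        return self.values.reshape(self.raster["nrows"], self.raster["ncols"])


def predict(
    model: LurModel,
    matrix: PredictorMatrix,
    *,
    truncate: bool = True,
    floor_zero: bool = True,
) -> PredictionGrid:
    """Evaluate a model on a predictor matrix.

    The matrix must contain every predictor the model selected (extra columns
    are ignored); a missing column raises :class:`SchemaError` naming it.
    With ``truncate`` each predictor is clamped to the model's training range
    before evaluation.
    """
    names = model.predictor_names
    missing = [n for n in names if n not in matrix.data.columns]
    if missing:
        raise SchemaError(f"matrix lacks predictors required by the model: {missing}")
    X = matrix.data[names].to_numpy(dtype=float) if names else np.zeros((len(matrix.data), 0))
    truncated = np.zeros(len(matrix.data), dtype=bool)
    if truncate and names and model.training_ranges:
        for j, n in enumerate(names):
            lo, hi = model.training_ranges.get(n, (-np.inf, np.inf))
            clipped = np.clip(X[:, j], lo, hi)
            truncated |= clipped != X[:, j]
            X[:, j] = clipped
    beta = np.asarray([float(model.fit.params[n]) for n in names])
    vals = model.intercept + (X @ beta if names else 0.0)
    vals = np.asarray(vals, dtype=float) + np.zeros(len(matrix.data))
    floored = np.zeros(len(vals), dtype=bool)
    if floor_zero:
        floored = vals < 0
        vals = np.where(floored, 0.0, vals)
    return PredictionGrid(
        list(matrix.data.index),
        vals,
        truncated,
        floored,
        model_id=f"{model.pollutant}:{model.scope}",
    )


def rasterize(
    model: LurModel,
    scene: CityScene,
    cell_size: float,
    *,
    truncate: bool = True,
    floor_zero: bool = True,
    quad_segs: int = 256,
) -> PredictionGrid:
    """Predict on a raster of cell centers covering the scene bounds.

    Builds only the model's own predictor columns at each cell center, then
    evaluates the model; deterministic for a fixed scene and model.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    x0, y0, x1, y1 = scene.bounds
    ncols = int(np.floor((x1 - x0) / cell_size))
    nrows = int(np.floor((y1 - y0) / cell_size))
    xs = x0 + (np.arange(ncols) + 0.5) * cell_size
    ys = y0 + (np.arange(nrows) + 0.5) * cell_size
    receptors = []
    k = 0
    for y in ys:
        for x in xs:
            receptors.append((f"c{k}", float(x), float(y)))
            k += 1
    if model.specs:
        matrix = build_predictor_matrix(receptors, scene, model.specs, quad_segs=quad_segs)
    else:
        data = pd.DataFrame(index=pd.Index([r[0] for r in receptors], name="receptor_id"))
        matrix = PredictorMatrix(data, [])
    grid = predict(model, matrix, truncate=truncate, floor_zero=floor_zero)
    grid.raster = {"x0": x0, "y0": y0, "cell": cell_size, "nrows": nrows, "ncols": ncols}
    return grid
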