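"""Plain-text model bundles.

A trained linear subset ensemble is serialized as a directory of
tab-separated per-subset files plus a JSON manifest, so any consumer (R,
awk, a spreadsheet) can read the weights.  For a linear kernel the full
predictive model is w, b, the Platt parameters (a, b_cal) and the
per-feature scaler, so prediction from a bundle reproduces the in-memory
model exactly.  Non-linear (RBF) models have no compact text form and are
refused.

Bundle layout::

    manifest.json              format version, kernel, C, subset scalars
    <subset>.tsv               category  feature  weight  mean  sd

Scalars per subset (bias, calibration a/b, training size) live in the
manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .features import FeatureMatrix, apply_scaler
from .models import SubsetModel

FORMAT_VERSION = 1


def save_bundle(models: dict[str, SubsetModel], outdir: str | Path, config: dict | None = None) -> Path:
    """Write a linear model ensemble as a text bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format_version": FORMAT_VERSION, "subsets": {}, "config": config or {}}
    for key, model in sorted(models.items()):
        if model.kernel != "linear":
            raise ValueError(
                f"subset {key}: only linear models have a text serialization"
            )
        w = np.asarray(model.svc.coef_).ravel()
        a, b_cal = model.calibration
        rows = []
        for (cat, name), weight in zip(model.retained_features, w):
            rows.append(
                {
                    "category": cat,
                    "feature": name,
                    "weight": weight,
                    "mean": model.scaler.loc["mean", (cat, name)],
                    "sd": model.scaler.loc["sd", (cat, name)],
                }
            )
        pd.DataFrame(rows).to_csv(outdir / f"{key}.tsv", sep="\t", index=False)
        manifest["subsets"][key] = {
            "bias": model.bias,
            "calibration_a": a,
            "calibration_b": b_cal,
            "n_training": model.n_training,
            "dropped_features": [list(f) for f in model.dropped_features],
        }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


@dataclass
class LinearBundleModel:
    """A linear subset model reloaded from its text form."""

    key: str
    features: list[tuple[str, str]]
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    bias: float
    calibration: tuple[float, float]
    dropped_features: list[tuple[str, str]]

    def predict_proba(self, M: FeatureMatrix) -> np.ndarray:
        """Calibrated P(disease) per row, identical to the source model."""
        X = M.df.loc[:, self.features].to_numpy()
        f = (X - self.means) / self.sds @ self.weights + self.bias
        a, b = self.calibration
        return expit(-(a * f + b))

    @property
    def categories(self) -> tuple[str, ...]:
        seen = dict.fromkeys(c for c, _ in self.features + self.dropped_features)
        return tuple(seen)


def load_bundle(bundle_dir: str | Path) -> dict[str, LinearBundleModel]:
    bundle_dir = Path(bundle_dir)
    manifest = json.loads((bundle_dir / "manifest.json").read_text())
    if manifest["format_version"] != FORMAT_VERSION:
        raise ValueError(f"unsupported bundle format {manifest['format_version']}")
    models: dict[str, LinearBundleModel] = {}
    for key, meta in manifest["subsets"].items():
        table = pd.read_csv(bundle_dir / f"{key}.tsv", sep="\t")
        models[key] = LinearBundleModel(
            key=key,
            features=[(r.category, r.feature) for r in table.itertuples()],
            weights=table["weight"].to_numpy(),
            means=table["mean"].to_numpy(),
            sds=table["sd"].to_numpy(),
            bias=meta["bias"],
            calibration=(meta["calibration_a"], meta["calibration_b"]),
            dropped_features=[tuple(f) for f in meta["dropped_features"]],
        )
    return models
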