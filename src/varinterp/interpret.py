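"""Feature-weight interpretation and the validating log-odds matrix.

For a linear maximum-margin classifier the weight vector can be recovered
from the dual solution,

    w = sum_i alpha_i * y_i * Phi(v_i),

summing over the support vectors with labels y_i in {-1, +1} and feature
maps Phi(v_i).  A positive weight marks a feature as disease-predictive,
a negative one as neutral-predictive.  Weight vectors are standardized to
zero mean and unit standard deviation per classifier so rows of different
subsets are comparable, and arranged into heat-map-ready tables ordered
either by a fixed amino-acid property ordering or by complete-linkage
hierarchical clustering.

The substitution-count log-odds matrix gives a model-free cross-check:
per (reference, mutant) pair, the log ratio of its class-normalised
frequency among disease vs neutral variants, masked to the 150
single-codon-mutation-reachable pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .genetic_code import AMINO_ACIDS, standard_reachability
from .io import DISEASE, NEUTRAL, VariantRecord
from .models import SubsetModel

AA_PROPERTY_ORDER: str = "DEKRHNQSTGACVILMPFYW"
"""Fixed amino-acid ordering by physicochemical property groups (charged,
polar, small, hydrophobic, aromatic); editable by downstream users."""


def extract_weights(model: SubsetModel) -> np.ndarray:
    """Reconstruct the primal weight vector from the dual coefficients.

    Only defined for the linear kernel; an RBF model has no feature-space
    weight vector to interpret.
    """
    if model.kernel != "linear":
        raise ValueError(
            f"weight extraction needs a linear kernel, got {model.kernel!r}"
        )
    w = model.support_coefficients @ model.svc.support_vectors_
    return np.asarray(w).ravel()


def primal_weights(model: SubsetModel) -> np.ndarray:
    """The solver's own primal coefficients (reference for the dual sum)."""
    if model.kernel != "linear":
        raise ValueError("primal weights undefined for non-linear kernels")
    return np.asarray(model.svc.coef_).ravel()


def standardize_weights(w: np.ndarray) -> np.ndarray:
    """Shift/scale a weight vector to zero mean, unit (population) sd."""
    w = np.asarray(w, dtype=float)
    finite = w[np.isfinite(w)]
    if finite.size < 2:
        raise ValueError("need at least 2 finite weights to standardize")
    sd = finite.std()
    if sd == 0:
        raise ValueError("constant weight vector cannot be standardized")
    return (w - finite.mean()) / sd


@dataclass
class WeightTable:
    """Subset-by-feature matrix of (standardized) weights.

    Masked cells (features removed as constant for a subset) are NaN.
    ``row_order``/``col_order`` hold the emission ordering.
    """

    df: pd.DataFrame
    standardized: bool = True

    @property
    def row_order(self) -> list[str]:
        return list(self.df.index)

    @property
    def col_order(self) -> list:
        return list(self.df.columns)

    def reordered(self, rows=None, cols=None) -> "WeightTable":
        df = self.df
        if rows is not None:
            df = df.loc[rows]
        if cols is not None:
            df = df.loc[:, cols]
        return WeightTable(df, standardized=self.standardized)


def weight_table(
    models: dict[str, SubsetModel],
    whole_model: SubsetModel | None = None,
    standardized: bool = True,
) -> WeightTable:
    """Assemble per-subset weight vectors into one table.

    Rows are aligned on the union of the models' feature names; a feature
    dropped as constant in some subset appears as a masked (NaN) cell in
    that row.  Masked cells are excluded from the row's standardization
    statistics.  The optional whole-set model is appended as row ``ALL``.
    """
    entries = list(models.items())
    if whole_model is not None:
        entries.append(("ALL", whole_model))
    categories = {
        tuple(sorted({c for c, _ in m.retained_features + m.dropped_features}))
        for _, m in entries
    }
    if len(categories) > 1:
        raise ValueError("models were trained on different feature categories")

    all_features = sorted(
        {f for _, m in entries for f in m.retained_features + m.dropped_features}
    )
    rows = {}
    for key, model in entries:
        w = extract_weights(model)
        if standardized:
            w = standardize_weights(w)
        row = pd.Series(np.nan, index=pd.MultiIndex.from_tuples(all_features))
        row.loc[model.retained_features] = w
        rows[key] = row
    df = pd.DataFrame(rows).T
    return WeightTable(df, standardized=standardized)


def ensemble_mean_weights(table: WeightTable) -> pd.Series:
    """Sign-consistent feature importance across the subset ensemble.

    The mean over subset rows of the standardized weight (masked cells
    skipped).  Features carrying a consistent signal keep their magnitude;
    features whose large weights are row-local noise (each row is scaled
    to unit sd, so an uninformative subset still contributes unit-scale
    weights) or collinearity artifacts cancel across rows.  Rank by the
    absolute value to find the dominant feature of a category.
    """
    return table.df.mean(axis=0, skipna=True)


def order_rows_cols(table: WeightTable, mode: str = "cluster") -> WeightTable:
    """Arrange a weight table for heat-map emission.

    ``aa_property`` applies the fixed :data:`AA_PROPERTY_ORDER` permutation
    to amino-acid-named rows/columns (non-amino-acid labels keep their
    position at the end, ``ALL`` always last).  ``cluster`` orders rows and
    columns by complete-linkage hierarchical clustering with Euclidean
    distance, imputing masked cells as 0 for the distance computation only.
    """
    df = table.df

    if mode == "aa_property":
        def aa_rank(label: str) -> tuple:
            name = label[1] if isinstance(label, tuple) else label
            name = name.lstrip("#")
            if name == "ALL":
                return (2, 0)
            i = AA_PROPERTY_ORDER.find(name)
            return (0, i) if i >= 0 else (1, str(name))

        rows = sorted(df.index, key=aa_rank)
        cols = sorted(df.columns, key=aa_rank)
        return table.reordered(rows, cols)

    if mode == "cluster":
        filled = df.fillna(0.0).to_numpy()
        rows = list(df.index)
        cols = list(df.columns)
        if len(rows) > 2:
            order = leaves_list(linkage(filled, method="complete", metric="euclidean"))
            rows = [rows[i] for i in order]
        if len(cols) > 2:
            order = leaves_list(linkage(filled.T, method="complete", metric="euclidean"))
            cols = [cols[i] for i in order]
        return table.reordered(rows, cols)

    raise ValueError(f"unknown ordering mode {mode!r}")


@dataclass
class LogOddsMatrix:
    """20x20 (reference x mutant) log-odds of disease vs neutral counts.

    Cells for substitutions unreachable by a single codon mutation are
    NaN; exactly 230 of the 380 off-diagonal cells are masked under the
    standard genetic code.
    """

    df: pd.DataFrame
    pseudocount: float = 0.5

    @property
    def mask(self) -> pd.DataFrame:
        return self.df.isna()


def log_odds_matrix(
    variants: list[VariantRecord], pseudocount: float = 0.5
) -> LogOddsMatrix:
    """Count substitutions per class and form the log-odds matrix.

    For reachable (r, m):  log[(d_rm + c) / (D + 380 c)] - log[(n_rm + c) /
    (N + 380 c)] with d/n the disease/neutral counts, D/N the class totals
    and c the pseudocount.  Positive values mark substitutions relatively
    enriched among disease-associated variants; the class-total
    normalisation makes the matrix insensitive to class imbalance.  With
    c = 0, cells with a zero count are +/-inf.
    """
    reach = standard_reachability()
    d_counts = np.zeros((20, 20))
    n_counts = np.zeros((20, 20))
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for v in variants:
        if v.label == DISEASE:
            d_counts[idx[v.ref_aa], idx[v.mut_aa]] += 1
        elif v.label == NEUTRAL:
            n_counts[idx[v.ref_aa], idx[v.mut_aa]] += 1
    D, N = d_counts.sum(), n_counts.sum()
    if D == 0 or N == 0:
        raise ValueError("both classes must be non-empty for log odds")
    c = pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log((d_counts + c) / (D + 380 * c)) - np.log(
            (n_counts + c) / (N + 380 * c)
        )
    values[~reach.reachable] = np.nan
    df = pd.DataFrame(values, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))
    return LogOddsMatrix(df, pseudocount=c)


def heatmap_emit(
    table: WeightTable | LogOddsMatrix, path: str | Path, title: str | None = None
) -> tuple[Path, Path]:
    """Write the numeric matrix (TSV, masked cells as NA) and a rendered
    diverging heat map (blue negative/neutral-predictive, red
    positive/disease-predictive).  Returns the two paths written."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    df = table.df.copy()
    if isinstance(df.columns, pd.MultiIndex):
        df.columns = [f"{c}:{n}" for c, n in df.columns]
    tsv_path = path.with_suffix(".tsv")
    df.to_csv(tsv_path, sep="\t", na_rep="NA")

    png_path = path.with_suffix(".png")
    finite = df.to_numpy()[np.isfinite(df.to_numpy())]
    vmax = float(np.abs(finite).max()) if finite.size else 1.0
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * len(df.columns) + 2), max(3, 0.25 * len(df) + 2))
    )
    im = ax.imshow(df.to_numpy(), cmap="bwr", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(df.columns)), df.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(df.index)), df.index, fontsize=6)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return tsv_path, png_path
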