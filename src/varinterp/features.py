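"""The five sequence-derived feature categories.

Each variant is encoded by up to 66 features in five blocks:

* ``substitution`` (20): reference amino acid -1, mutant +1, others 0.
* ``surrounding`` (20): amino-acid counts in a 19-residue window around
  the substituted position.
* ``conservation`` (4): frequency of the reference and the mutant amino
  acid in the MSA column at the position, the number of aligned proteins,
  and the number of non-gap residues in the column.
* ``physchem`` (K=19): per amino-acid scale, the minimal absolute scale
  distance between the mutant amino acid and any residue observed in the
  MSA column.
* ``domain`` (3): binary membership of the position in a Pfam family,
  domain or clan annotation.

Features are assembled into a :class:`FeatureMatrix` (a thin wrapper over
a pandas DataFrame with (category, name) columns), constant columns are
dropped per training subset, and the remainder standardized to zero mean
and unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_code import AMINO_ACIDS
from .io import Msa, MsaColumn, PfamAnnotation, ScaleSet, VariantRecord

CATEGORIES = ("substitution", "surrounding", "conservation", "physchem", "domain")

CONSERVATION_NAMES = ("f_ref", "f_mut", "n_proteins", "n_residues")
DOMAIN_NAMES = ("family", "domain", "clan")

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class WindowSpec:
    """Sequence window around the substituted residue.

    ``length`` residues centred on the position (odd, default 19, i.e.
    nine on each side); ``include_center`` controls whether the substituted
    residue itself is counted.
    """

    length: int = 19
    include_center: bool = True

    def __post_init__(self) -> None:
        if self.length < 3 or self.length % 2 == 0:
            raise ValueError("window length must be an odd integer >= 3")


def substitution_features(v: VariantRecord) -> np.ndarray:
    """20-vector with -1 at the reference and +1 at the mutant amino acid."""
    if v.ref_aa not in _AA_INDEX or v.mut_aa not in _AA_INDEX:
        raise ValueError(f"{v.variant_id}: non-standard amino acid")
    x = np.zeros(20)
    x[_AA_INDEX[v.ref_aa]] = -1.0
    x[_AA_INDEX[v.mut_aa]] = 1.0
    return x


def surrounding_features(
    v: VariantRecord, protein_seq: str, spec: WindowSpec = WindowSpec()
) -> np.ndarray:
    """Amino-acid counts in the window around the variant, truncated at
    the sequence ends."""
    half = spec.length // 2
    lo = max(1, v.position - half)
    hi = min(len(protein_seq), v.position + half)
    x = np.zeros(20)
    for pos in range(lo, hi + 1):
        if pos == v.position and not spec.include_center:
            continue
        aa = protein_seq[pos - 1]
        if aa in _AA_INDEX:
            x[_AA_INDEX[aa]] += 1.0
    return x


def conservation_features(
    v: VariantRecord, col: MsaColumn, denominator: str = "n_residues"
) -> np.ndarray:
    """(f_ref, f_mut, n_proteins, n_residues) from the MSA column.

    Frequencies are over the non-gap residues in the column by default
    (``denominator="n_proteins"`` divides by the alignment depth instead);
    both are 0 for an empty column.
    """
    denom = col.n_residues if denominator == "n_residues" else col.n_proteins
    if denom:
        f_ref = col.residues.get(v.ref_aa, 0) / denom
        f_mut = col.residues.get(v.mut_aa, 0) / denom
    else:
        f_ref = f_mut = 0.0
    return np.array([f_ref, f_mut, float(col.n_proteins), float(col.n_residues)])


def physchem_features(v: VariantRecord, col: MsaColumn, scales: ScaleSet) -> np.ndarray:
    """Minimal absolute scale distance from the mutant amino acid to any
    residue observed in the column, per scale; 0 for an empty column."""
    observed = [aa for aa in col.residues if aa in _AA_INDEX]
    x = np.zeros(len(scales))
    if not observed:
        return x
    for k, name in enumerate(scales.names):
        mut_val = scales.value(name, v.mut_aa)
        x[k] = min(abs(mut_val - scales.value(name, aa)) for aa in observed)
    return x


def domain_features(v: VariantRecord, annotations: list[PfamAnnotation]) -> np.ndarray:
    """Binary (family, domain, clan) membership of the variant position."""
    x = np.zeros(3)
    for ann in annotations:
        if ann.protein_id == v.protein_id and ann.covers(v.position):
            if ann.match_type == "family":
                x[0] = 1.0
            elif ann.match_type == "domain":
                x[1] = 1.0
            else:
                x[2] = 1.0
    return x


Scaler = pd.DataFrame  # columns: feature MultiIndex; rows: "mean", "sd"


@dataclass
class FeatureMatrix:
    """Variant-by-feature matrix with (category, name) column labels."""

    df: pd.DataFrame
    scaler: Scaler | None = None

    @property
    def feature_names(self) -> list[tuple[str, str]]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def category(self, name: str) -> "FeatureMatrix":
        """Restrict to one feature category."""
        return FeatureMatrix(self.df[[c for c in self.df.columns if c[0] == name]])

    def to_tsv(self, path) -> None:
        """Two-row header (category, feature name), then one row per variant."""
        out = self.df.copy()
        out.columns = pd.MultiIndex.from_tuples(out.columns)
        out.to_csv(path, sep="\t", index_label="variant_id")


@dataclass
class Resources:
    """Everything feature assembly needs, indexed by protein id."""

    proteins: dict[str, str]
    msas: dict[str, Msa]
    pfam: dict[str, list[PfamAnnotation]] = field(default_factory=dict)
    scales: ScaleSet | None = None
    window: WindowSpec = field(default_factory=WindowSpec)
    conservation_denominator: str = "n_residues"

    @classmethod
    def with_default_scales(cls, proteins, msas, pfam=None, **kw) -> "Resources":
        from .scales import default_scales

        return cls(proteins, msas, pfam or {}, default_scales(), **kw)


def assemble(
    variants: list[VariantRecord],
    resources: Resources,
    categories: tuple[str, ...] = CATEGORIES,
) -> tuple[FeatureMatrix, list[str]]:
    """Build the feature matrix for ``variants``.

    Column order is deterministic (category blocks in the canonical order,
    fixed name order within); rows follow input order.  Variants whose
    protein sequence or MSA is missing are skipped and listed in the
    returned exclusion report.
    """
    unknown = set(categories) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown feature categories: {sorted(unknown)}")
    need_msa = "conservation" in categories or "physchem" in categories
    if "physchem" in categories and resources.scales is None:
        raise ValueError("physchem features requested but no scales loaded")

    columns: list[tuple[str, str]] = []
    for cat in CATEGORIES:
        if cat not in categories:
            continue
        if cat == "substitution":
            columns += [(cat, aa) for aa in AMINO_ACIDS]
        elif cat == "surrounding":
            columns += [(cat, f"#{aa}") for aa in AMINO_ACIDS]
        elif cat == "conservation":
            columns += [(cat, n) for n in CONSERVATION_NAMES]
        elif cat == "physchem":
            columns += [(cat, n) for n in resources.scales.names]
        elif cat == "domain":
            columns += [(cat, n) for n in DOMAIN_NAMES]

    rows: list[np.ndarray] = []
    ids: list[str] = []
    excluded: list[str] = []
    for v in variants:
        seq = resources.proteins.get(v.protein_id)
        if seq is None:
            excluded.append(f"{v.variant_id}: no protein sequence")
            continue
        msa = resources.msas.get(v.protein_id) if need_msa else None
        if need_msa:
            if msa is None:
                excluded.append(f"{v.variant_id}: no MSA")
                continue
            if v.position > len(msa):
                excluded.append(f"{v.variant_id}: position beyond MSA")
                continue
        parts: list[np.ndarray] = []
        for cat in CATEGORIES:
            if cat not in categories:
                continue
            if cat == "substitution":
                parts.append(substitution_features(v))
            elif cat == "surrounding":
                parts.append(surrounding_features(v, seq, resources.window))
            elif cat == "conservation":
                parts.append(
                    conservation_features(
                        v, msa.column(v.position), resources.conservation_denominator
                    )
                )
            elif cat == "physchem":
                parts.append(physchem_features(v, msa.column(v.position), resources.scales))
            elif cat == "domain":
                parts.append(domain_features(v, resources.pfam.get(v.protein_id, [])))
        rows.append(np.concatenate(parts))
        ids.append(v.variant_id)

    df = pd.DataFrame(
        np.array(rows) if rows else np.empty((0, len(columns))),
        index=ids,
        columns=pd.MultiIndex.from_tuples(columns, names=["category", "feature"]),
    )
    return FeatureMatrix(df), excluded


def drop_constant_columns(M: FeatureMatrix) -> tuple[FeatureMatrix, list[tuple[str, str]]]:
    """Remove zero-variance columns; they carry no class information for
    the subset the matrix was built on.

    Returns the reduced matrix and the dropped column names (retained so a
    prediction-time matrix can be aligned to the training columns).
    """
    values = M.df.to_numpy()
    constant = values.min(axis=0) == values.max(axis=0)
    if constant.all():
        raise ValueError("all feature columns are constant; nothing to train on")
    dropped = [c for c, is_const in zip(M.df.columns, constant) if is_const]
    return FeatureMatrix(M.df.loc[:, ~constant]), dropped


def standardize(M: FeatureMatrix) -> tuple[FeatureMatrix, Scaler]:
    """Zero-mean unit-variance scaling (population sd), fitted on ``M``."""
    mean = M.df.mean(axis=0)
    sd = M.df.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = [c for c, s in sd.items() if s == 0]
        raise ValueError(f"constant columns must be dropped before scaling: {bad}")
    scaler = pd.DataFrame({"mean": mean, "sd": sd}).T
    scaled = (M.df - mean) / sd
    return FeatureMatrix(scaled, scaler=scaler), scaler


def apply_scaler(M: FeatureMatrix, scaler: Scaler) -> FeatureMatrix:
    """Re-apply a fitted scaler verbatim (e.g. to CV test rows)."""
    if list(M.df.columns) != list(scaler.columns):
        raise ValueError("scaler columns do not match the feature matrix")
    scaled = (M.df - scaler.loc["mean"]) / scaler.loc["sd"]
    return FeatureMatrix(scaled, scaler=scaler)
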