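"""Synthetic proteins, alignments, annotations and labeled variants.

The generator emulates the shape of a real variant-effect study — protein
FASTA, per-protein MSAs with controllable per-column conservation,
Pfam-like interval annotations, and labeled missense variants — with a
*planted* feature-label structure: the disease label of each variant is
drawn from a logistic model over its true feature values, so the Bayes
optimal discrimination (and hence the AUC a perfect classifier could
attain) is known and tunable.

Model per variant i with standardized planted-feature values z_ij:

    P(disease | v_i) = sigmoid(b0 + sum_j beta_j m_{s(i),j} z_ij)

where beta_j are the planted log-odds effect sizes, m_{s,j} optional
per-subset multipliers (``subset_heterogeneity`` > 0 makes feature effects
differ between reference-amino-acid subsets, which a single global linear
model cannot represent), and b0 is calibrated so the expected disease
fraction matches ``class_balance``.

Variants are only drawn among single-codon-mutation-reachable amino-acid
pairs at positions whose reference matches the sequence, so a generated
dataset passes the filtering pipeline without sequence-fit removals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .features import FeatureMatrix, Resources, WindowSpec, assemble
from .genetic_code import AMINO_ACIDS, reachable_mutants
from .io import (
    Msa,
    PfamAnnotation,
    ScaleSet,
    VariantRecord,
    msa_from_rows,
    write_fasta,
    write_labeled_variants,
    write_pfam_table,
)

#: One planted effect per feature category; log-odds per sd of the feature.
DEFAULT_PLANTED_EFFECTS: tuple[tuple[tuple[str, str], float], ...] = (
    (("substitution", "P"), 1.0),
    (("surrounding", "#C"), 1.0),
    (("conservation", "f_ref"), 2.5),
    (("physchem", "scale_3"), 1.5),
    (("domain", "domain"), 1.0),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_proteins: int = 40
    protein_length: tuple[int, int] = (200, 400)
    n_variants: int = 20_000
    class_balance: float = 0.125  # disease fraction, matching real catalogues
    planted_effects: tuple[tuple[tuple[str, str], float], ...] = DEFAULT_PLANTED_EFFECTS
    msa_depth: tuple[int, int] = (5, 50)
    conservation: tuple[float, float] = (0.1, 0.95)  # per-column copy probability
    gap_prob: float = 0.1
    pfam_coverage: float = 0.3
    subset_heterogeneity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")
        lo, hi = self.conservation
        if not (0 <= lo <= hi <= 1):
            raise ValueError("conservation range must lie in [0, 1]")
        if not 0 <= self.gap_prob < 1:
            raise ValueError("gap_prob must be in [0, 1)")
        for _, beta in self.planted_effects:
            if not np.isfinite(beta):
                raise ValueError("planted effect sizes must be finite")


@dataclass
class SyntheticDataset:
    """A generated study: inputs for every pipeline stage plus the truth."""

    config: GeneratorConfig
    proteins: dict[str, str]
    msas: dict[str, Msa]
    pfam: list[PfamAnnotation]
    variants: list[VariantRecord]  # labeled
    probabilities: np.ndarray  # true P(disease) per variant
    true_features: FeatureMatrix
    subset_multipliers: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=dict
    )

    def resources(self, scales: ScaleSet | None = None, **kw) -> Resources:
        pfam_by_protein: dict[str, list[PfamAnnotation]] = {}
        for ann in self.pfam:
            pfam_by_protein.setdefault(ann.protein_id, []).append(ann)
        if scales is None:
            from .scales import default_scales

            scales = default_scales()
        return Resources(self.proteins, self.msas, pfam_by_protein, scales, **kw)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit proteins.fasta, msa/<id>.fasta, pfam.tsv and variants.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.fasta",
            "pfam": outdir / "pfam.tsv",
            "variants": outdir / "variants.tsv",
            "msa_dir": outdir / "msa",
        }
        write_fasta(self.proteins, paths["fasta"])
        write_pfam_table(self.pfam, paths["pfam"])
        write_labeled_variants(self.variants, paths["variants"])
        paths["msa_dir"].mkdir(exist_ok=True)
        for pid, rows in self._msa_rows.items():
            with open(paths["msa_dir"] / f"{pid}.fasta", "w") as fh:
                for k, seq in enumerate(rows):
                    fh.write(f">{pid if k == 0 else f'{pid}_hom{k}'}\n{seq}\n")
        return paths

    _msa_rows: dict[str, list[str]] = field(default_factory=dict, repr=False)


def _generate_proteins(cfg: GeneratorConfig, rng) -> dict[str, str]:
    aas = np.array(list(AMINO_ACIDS))
    lo, hi = cfg.protein_length
    proteins = {}
    for i in range(cfg.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        proteins[f"SYN{i:04d}"] = "".join(rng.choice(aas, size=length))
    return proteins


def _generate_msa(seq: str, cfg: GeneratorConfig, rng) -> list[str]:
    """Aligned rows (query first) under the copy-with-probability model."""
    depth = int(rng.integers(cfg.msa_depth[0], cfg.msa_depth[1] + 1))
    n_hom = max(0, depth - 1)
    L = len(seq)
    alpha = rng.uniform(cfg.conservation[0], cfg.conservation[1], size=L)
    aas = np.array(list(AMINO_ACIDS))
    query = np.array(list(seq))
    rows = [seq]
    for _ in range(n_hom):
        gaps = rng.random(L) < cfg.gap_prob
        copies = rng.random(L) < alpha
        residues = np.where(copies, query, rng.choice(aas, size=L))
        residues[gaps] = "-"
        rows.append("".join(residues))
    return rows


def _generate_pfam(proteins: dict[str, str], cfg: GeneratorConfig, rng) -> list[PfamAnnotation]:
    annotations = []
    match_types = ("family", "domain", "clan-member")
    for pid, seq in proteins.items():
        L = len(seq)
        covered = 0
        cursor = 1
        while covered < cfg.pfam_coverage * L and cursor < L - 30:
            start = cursor + int(rng.integers(0, 40))
            span = int(rng.integers(30, 81))
            end = min(L, start + span - 1)
            if start >= end:
                break
            mtype = match_types[int(rng.integers(0, 3))]
            clan = f"CL{int(rng.integers(0, 50)):04d}" if mtype == "clan-member" else None
            annotations.append(PfamAnnotation(pid, start, end, mtype, clan))
            covered += end - start + 1
            cursor = end + 1
    return annotations


def _draw_variants(proteins: dict[str, str], cfg: GeneratorConfig, rng) -> list[VariantRecord]:
    pids = sorted(proteins)
    reachable = {aa: sorted(reachable_mutants(aa)) for aa in AMINO_ACIDS}
    seen: set[tuple] = set()
    variants: list[VariantRecord] = []
    attempts = 0
    max_attempts = 50 * cfg.n_variants
    while len(variants) < cfg.n_variants:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "infeasible config: cannot draw enough distinct variants"
            )
        pid = pids[int(rng.integers(0, len(pids)))]
        seq = proteins[pid]
        pos = int(rng.integers(2, len(seq) + 1))  # never the start codon
        ref = seq[pos - 1]
        muts = reachable[ref]
        mut = muts[int(rng.integers(0, len(muts)))]
        key = (pid, pos, ref, mut)
        if key in seen:
            continue
        seen.add(key)
        variants.append(VariantRecord(pid, pos, ref, mut))
    return variants


def _subset_multipliers(cfg: GeneratorConfig, rng) -> dict[str, dict[tuple[str, str], float]]:
    from .models import SUBSET_KEYS

    h = cfg.subset_heterogeneity
    multipliers: dict[str, dict[tuple[str, str], float]] = {}
    for key in SUBSET_KEYS:
        multipliers[key] = {
            feat: 1.0 + h * float(rng.uniform(-1.0, 1.0)) if h > 0 else 1.0
            for feat, _ in cfg.planted_effects
        }
    return multipliers


def generate(cfg: GeneratorConfig, scales: ScaleSet | None = None) -> SyntheticDataset:
    """Generate one synthetic study; byte-identical for a fixed config."""
    from .models import subset_of

    rng = np.random.default_rng(cfg.seed)
    proteins = _generate_proteins(cfg, rng)
    msa_rows = {pid: _generate_msa(seq, cfg, rng) for pid, seq in proteins.items()}
    msas = {pid: msa_from_rows(pid, rows) for pid, rows in msa_rows.items()}
    pfam = _generate_pfam(proteins, cfg, rng)
    variants = _draw_variants(proteins, cfg, rng)
    multipliers = _subset_multipliers(cfg, rng)

    dataset = SyntheticDataset(
        config=cfg,
        proteins=proteins,
        msas=msas,
        pfam=pfam,
        variants=variants,
        probabilities=np.array([]),
        true_features=None,  # filled below
        subset_multipliers=multipliers,
    )
    dataset._msa_rows = msa_rows

    resources = dataset.resources(scales=scales)
    M, excluded = assemble(variants, resources)
    if excluded:
        raise AssertionError(f"generator produced unfeaturizable variants: {excluded[:3]}")
    dataset.true_features = M

    # Planted logistic label model over true feature values, z-scored over
    # the generated set so every beta is a per-sd log-odds effect.
    eta = np.zeros(len(variants))
    for feat, beta in cfg.planted_effects:
        if feat not in M.df.columns:
            raise ValueError(f"planted feature {feat} not among generated features")
        x = M.df[feat].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"infeasible config: planted feature {feat} is constant")
        z = (x - x.mean()) / sd
        m = np.array([multipliers[subset_of(v.ref_aa)][feat] for v in variants])
        eta += beta * m * z

    def mean_prob(b0: float) -> float:
        return float(expit(b0 + eta).mean())

    b0 = brentq(lambda b: mean_prob(b) - cfg.class_balance, -30.0, 30.0)
    p = expit(b0 + eta)
    labels = (rng.random(len(variants)) < p).astype(int)
    dataset.variants = [v.with_label(int(y)) for v, y in zip(variants, labels)]
    dataset.probabilities = p
    return dataset


def oracle_auc(cfg: GeneratorConfig, n_label_draws: int = 20) -> float:
    """Monte-Carlo estimate of the Bayes-optimal AUC for a config.

    The optimal score is the true P(disease); labels are redrawn from it
    ``n_label_draws`` times and the AUCs averaged.  0.5 when no effect is
    planted; approaches 1 as effects grow.
    """
    dataset = generate(cfg)
    p = dataset.probabilities
    if np.allclose(p, p[0]):
        return 0.5
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB5]))
    aucs = []
    for _ in range(n_label_draws):
        labels = (rng.random(len(p)) < p).astype(int)
        if labels.min() == labels.max():
            continue
        aucs.append(roc_auc_score(labels, p))
    return float(np.mean(aucs)) if aucs else 0.5
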