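import numpy as np
import pytest
from hypothesis import settings

from varinterp.features import Resources, WindowSpec
from varinterp.io import Msa, MsaColumn, PfamAnnotation, ScaleSet, VariantRecord, msa_from_rows

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_proteins() -> dict[str, str]:
    return {
        "P1": "MKVAAAAAAAAAAAAAAAAAAAAAAAAAAAGT",  # poly-A core
        "P2": "MACDEFGHIKLMNPQRSTVWYACDEFGHIKLM",
        "P3": "MSSSSSSSSSSSSSSSSSSSS",
    }


@pytest.fixture(scope="session")
def toy_msas(toy_proteins) -> dict[str, Msa]:
    msas = {}
    for pid, seq in toy_proteins.items():
        homolog = seq[:-1] + "-"  # last column gapped in the homolog
        msas[pid] = msa_from_rows(pid, [seq, homolog])
    return msas


@pytest.fixture(scope="session")
def toy_scales() -> ScaleSet:
    rng = np.random.default_rng(7)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    values = {
        "s1": dict(zip(aas, np.linspace(0.0, 2.0, 20))),
        "s2": dict(zip(aas, rng.standard_normal(20).round(3))),
    }
    return ScaleSet(names=("s1", "s2"), values=values)


@pytest.fixture(scope="session")
def toy_resources(toy_proteins, toy_msas, toy_scales) -> Resources:
    pfam = {
        "P2": [
            PfamAnnotation("P2", 5, 20, "domain"),
            PfamAnnotation("P2", 10, 30, "clan-member", "CL0001"),
        ]
    }
    return Resources(toy_proteins, toy_msas, pfam, toy_scales, WindowSpec())


@pytest.fixture(scope="session")
def small_dataset():
    """A small generated study shared by model-level tests."""
    from varinterp.simulate import GeneratorConfig, generate

    return generate(GeneratorConfig(n_variants=2500, seed=42))


def make_variant(protein="P2", position=5, ref=None, mut="G", label=1, seq=None):
    if ref is None:
        ref = (seq or "MACDEFGHIKLMNPQRSTVWYACDEFGHIKLM")[position - 1]
    return VariantRecord(protein, position, ref, mut, label=label)


def matrix(X):
    """Wrap a plain array as a one-category FeatureMatrix."""
    import pandas as pd

    from varinterp.features import FeatureMatrix

    X = np.asarray(X, dtype=float)
    cols = pd.MultiIndex.from_tuples([("x", f"f{i}") for i in range(X.shape[1])])
    return FeatureMatrix(pd.DataFrame(X, columns=cols))


def separable_toy(n=40, seed=0):
    """Two widely separated Gaussian clouds; labels follow the first axis."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 2))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += np.where(y, 2.0, -2.0)
    return matrix(X), y
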