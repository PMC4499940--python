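import numpy as np
import pytest

from gsoa import ClassLabels, ClassifierConfig, OmicMatrix


def make_noise_matrix(n_genes: int, n_samples: int, seed: int,
                      name: str = "noise") -> OmicMatrix:
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i + 1:05d}" for i in range(n_genes)], dtype=object)
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    return OmicMatrix(name, samples, genes,
                      rng.standard_normal((n_genes, n_samples)))


def make_balanced_labels(sample_ids) -> ClassLabels:
    half = len(sample_ids) // 2
    return ClassLabels(
        {s: ("ctrl" if i < half else "case")
         for i, s in enumerate(sample_ids)},
        positive_class="ctrl")  # lexicographically second of {case, ctrl}


@pytest.fixture
def default_cfg() -> ClassifierConfig:
    return ClassifierConfig(seed=7)


@pytest.fixture
def tiny_matrix_file(tmp_path):
    path = tmp_path / "expr.txt"
    path.write_text(
        "S1\tS2\tS3\n"
        "TP53\t1.0\t2.0\t3.0\n"
        "TP53\t0.5\t0.5\t0.5\n"
        "MDM2\t-1.0\t0.0\t1.5\n")
    return str(path)


@pytest.fixture
def tiny_class_file(tmp_path):
    path = tmp_path / "classes.txt"
    path.write_text("S1\tcase\nS2\tcase\nS3\tctrl\nS4\tctrl\n")
    return str(path)


@pytest.fixture
def tiny_gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "P53_PATHWAY\tcurated\tTP53\tMDM2\tCDKN1A\n"
        "DUP_SET\td\tA\tA\tB\n")
    return str(path)
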