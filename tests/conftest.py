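import numpy as np
import pytest

from rbpknn.motifs import BACKGROUND_RATIO, PROBABILITY, PWM, RBPRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_probability_pwm(rng: np.random.Generator, k: int = 7, motif_id: str = "m") -> PWM:
    cols = rng.dirichlet(np.full(4, 0.6), size=k).T
    cols = (cols + 1e-4) / (1 + 4e-4)
    return PWM(cols, PROBABILITY, motif_id)


def random_background_pwm(rng: np.random.Generator, k: int = 7, motif_id: str = "m") -> PWM:
    return random_probability_pwm(rng, k, motif_id).to_background_ratio()


def random_protein(rng: np.random.Generator, length: int = 60) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=length))


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def pwm_factory():
    return random_probability_pwm


@pytest.fixture
def small_family(rng):
    """Five homologs with attached PWMs plus a query, sequences related by
    point substitutions so similarities are graded."""
    base = random_protein(rng, 80)

    def mutate(seq: str, n_subs: int) -> str:
        seq = list(seq)
        pos = rng.choice(len(seq), size=n_subs, replace=False)
        for p in pos:
            seq[p] = AA20[(AA20.index(seq[p]) + 1 + int(rng.integers(0, 18))) % 20]
        return "".join(seq)

    homologs = [
        RBPRecord(
            rbp_id=f"H{i}",
            aa_sequence=mutate(base, 5 * (i + 1)),
            family="RRM",
            construct="FL",
            pwm=random_probability_pwm(rng, 7, f"H{i}"),
        )
        for i in range(5)
    ]
    query = RBPRecord(rbp_id="Q", aa_sequence=base, family="RRM", construct="FL")
    return query, homologs
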