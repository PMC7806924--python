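import numpy as np
import pytest

from pedherit import Individual, Pedigree, Sex, compute_kinship


@pytest.fixture
def trio():
    """Father, mother, one child."""
    return Pedigree([
        Individual("dad", "FAM1", None, None, Sex.MALE),
        Individual("mom", "FAM1", None, None, Sex.FEMALE),
        Individual("kid", "FAM1", "dad", "mom", Sex.FEMALE),
    ])


@pytest.fixture
def two_generation():
    """Two founder couples, sibs, half sibs and first cousins.

    f1 x m1 -> a, b, e        (a, b, e full sibs)
    f1 x m2 -> c              (half sib of a, b, e)
    a  x s1 -> d1, d2         (sibs; first cousins of g)
    b  x s2 -> g
    """
    return Pedigree([
        Individual("f1", "F", None, None, Sex.MALE),
        Individual("m1", "F", None, None, Sex.FEMALE),
        Individual("m2", "F", None, None, Sex.FEMALE),
        Individual("s1", "F", None, None, Sex.MALE),
        Individual("s2", "F", None, None, Sex.FEMALE),
        Individual("a", "F", "f1", "m1", Sex.FEMALE),
        Individual("b", "F", "f1", "m1", Sex.MALE),
        Individual("e", "F", "f1", "m1", Sex.MALE),
        Individual("c", "F", "f1", "m2", Sex.FEMALE),
        Individual("d1", "F", "s1", "a", Sex.MALE),
        Individual("d2", "F", "s1", "a", Sex.FEMALE),
        Individual("g", "F", "b", "s2", Sex.MALE),
    ])


@pytest.fixture
def sib_quads():
    """Two families of two founder parents plus two full sibs each (8 ids)."""
    rows = []
    for fam in ("A", "B"):
        rows += [
            Individual(f"{fam}f", fam, None, None, Sex.MALE),
            Individual(f"{fam}m", fam, None, None, Sex.FEMALE),
            Individual(f"{fam}c1", fam, f"{fam}f", f"{fam}m", Sex.MALE),
            Individual(f"{fam}c2", fam, f"{fam}f", f"{fam}m", Sex.FEMALE),
        ]
    return Pedigree(rows)


def sib_pair_cohort(n_families: int, rng, h2: float, sibs: int = 2):
    """Pedigree of nuclear families plus a trait drawn from the polygenic model.

    Children AND parents are phenotyped (simple direct draw through family
    Cholesky); returns (pedigree, kinship, y aligned to kinship ids).
    """
    rows = []
    for k in range(n_families):
        fam = f"N{k}"
        rows += [
            Individual(f"{fam}f", fam, None, None, Sex.MALE),
            Individual(f"{fam}m", fam, None, None, Sex.FEMALE),
        ]
        rows += [
            Individual(f"{fam}c{j}", fam, f"{fam}f", f"{fam}m", Sex.MALE)
            for j in range(sibs)
        ]
    ped = Pedigree(rows)
    kin = compute_kinship(ped)
    K = 2.0 * kin.values
    y = np.empty(len(ped))
    for block in kin.family_blocks():
        Kb = K[np.ix_(block, block)]
        w, U = np.linalg.eigh(Kb)
        A = U * np.sqrt(np.clip(w, 0, None))
        g = A @ rng.standard_normal(len(block))
        y[block] = np.sqrt(h2) * g + np.sqrt(1 - h2) * rng.standard_normal(len(block))
    return ped, kin, y
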