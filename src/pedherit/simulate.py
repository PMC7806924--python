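"""Synthetic family-cohort generator.

Emulates an extended Mexican-American family study of school-age children:
~401 nuclear families/sibships embedded in extended families, ~1.7 children
per nuclear family (range 1-5, ~670 phenotyped children in total), children
aged 6-17, and multivariate phenotypes generated from the polygenic model
with declared per-trait heritabilities and genetic/environmental correlation
matrices. Consecutive nuclear families are linked into extended families by
making one parent of the next family an extra offspring of the previous
couple, which creates avuncular and cousin pairs among the study children.

Phenotypes are drawn exactly from the model the estimators assume: per-family
genetic effects g ~ MVN(0, G (x) 2*Phi) and independent environmental effects
e ~ MVN(0, E (x) I), with G = Dh * rho_G * Dh (Dh = diag(sqrt(h2))) and E the
analogue with 1 - h2, so each latent trait has unit variance and additive
fraction h2. Observed traits are an affine (identity) or log-normal (exp)
transform of the latent plus small age/sex effects. All randomness flows from
one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Individual, KinshipMatrix, Pedigree, Sex, compute_kinship

#: default children-per-nuclear-family distribution (range 1-5, mean 1.66 so
#: that 401 families yield ~670 children)
DEFAULT_CHILD_PROBS = {1: 0.55, 2: 0.30, 3: 0.10, 4: 0.04, 5: 0.01}


@dataclass
class TraitGenSpec:
    """Generative model for one trait.

    ``mean``/``sd`` are on the observed scale; ``h2`` is the additive
    fraction of the unit-variance latent; ``transform`` is "identity"
    (observed = mean + sd * latent) or "exp" (log-normal with matching
    observed mean and sd). ``age_beta`` (per year, latent SD units) and
    ``sex_beta`` (girls vs boys, latent SD units) shift the latent before
    the transform.
    """

    name: str
    mean: float
    sd: float
    h2: float
    transform: str = "identity"
    age_beta: float = 0.0
    sex_beta: float = 0.0

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"{self.name}: h2 must lie in [0, 1]")
        if self.transform not in ("identity", "exp"):
            raise ValueError(f"{self.name}: unknown transform {self.transform!r}")


@dataclass
class CorrelationStructure:
    """Genetic and environmental correlation matrices over declared traits."""

    names: list[str]
    rho_g: np.ndarray
    rho_e: np.ndarray

    def __post_init__(self):
        k = len(self.names)
        for label, m in (("rho_g", self.rho_g), ("rho_e", self.rho_e)):
            m = np.asarray(m, dtype=float)
            setattr(self, label, m)
            if m.shape != (k, k):
                raise ValueError(f"{label} must be {k}x{k}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{label} must be symmetric")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError(f"{label} must have unit diagonal")
            if np.linalg.eigvalsh(m).min() < -1e-8:
                raise ValueError(f"{label} is not positive semi-definite")

    @classmethod
    def independent(cls, names: list[str]) -> "CorrelationStructure":
        k = len(names)
        return cls(list(names), np.eye(k), np.eye(k))

    @classmethod
    def from_pairs(cls, names, rho_g_pairs=None, rho_e_pairs=None):
        """Build from {(a, b): rho} dicts; unspecified entries are 0."""
        k = len(names)
        idx = {n: i for i, n in enumerate(names)}
        mats = []
        for pairs in (rho_g_pairs or {}, rho_e_pairs or {}):
            m = np.eye(k)
            for (a, b), r in pairs.items():
                m[idx[a], idx[b]] = m[idx[b], idx[a]] = r
            mats.append(m)
        return cls(list(names), *mats)

    def implied_phenotypic(self, h2: np.ndarray) -> np.ndarray:
        """Entrywise decomposition-implied phenotypic correlation matrix."""
        h2 = np.asarray(h2, dtype=float)
        dh = np.sqrt(h2)
        de = np.sqrt(1.0 - h2)
        return (np.outer(dh, dh) * self.rho_g) + (np.outer(de, de) * self.rho_e)


@dataclass
class CohortSpec:
    """Study-design parameters of the synthetic cohort."""

    n_nuclear_families: int = 401
    children_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CHILD_PROBS)
    )
    extended_linking: float = 0.3
    age_range: tuple[float, float] = (6.0, 17.0)
    girl_fraction: float = 0.493
    seed: int | None = None

    def __post_init__(self):
        probs = np.array(list(self.children_probs.values()), dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("children_probs must be a probability distribution")
        if not 0.0 <= self.extended_linking <= 1.0:
            raise ValueError("extended_linking must lie in [0, 1]")
        if not 0.0 <= self.girl_fraction <= 1.0:
            raise ValueError("girl_fraction must lie in [0, 1]")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_pedigree(spec: CohortSpec, rng=None) -> Pedigree:
    """Generate nuclear families chained into extended families.

    With probability ``extended_linking`` a nuclear family's mother or father
    is created as an extra offspring of the previous family's couple (sharing
    that family's extended id), so the two sibships become avuncular and
    further chained sibships become cousins.
    """
    rng = _rng(spec.seed if rng is None else rng)
    sizes = np.array(sorted(spec.children_probs))
    probs = np.array([spec.children_probs[s] for s in sizes], dtype=float)

    individuals: list[Individual] = []
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"I{counter:05d}"

    prev_couple = None  # (family_id, father_id, mother_id)
    ext = 0
    for _ in range(spec.n_nuclear_families):
        link = prev_couple is not None and rng.random() < spec.extended_linking
        if link:
            fam, pf, pm = prev_couple
            # linking parent: full sib of the previous family's children
            link_sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
            linker = Individual(new_id(), fam, pf, pm, link_sex)
            spouse = Individual(
                new_id(), fam, None, None,
                Sex.MALE if link_sex == Sex.FEMALE else Sex.FEMALE,
            )
            individuals += [linker, spouse]
            father, mother = (
                (linker, spouse) if link_sex == Sex.MALE else (spouse, linker)
            )
        else:
            ext += 1
            fam = f"F{ext:04d}"
            father = Individual(new_id(), fam, None, None, Sex.MALE)
            mother = Individual(new_id(), fam, None, None, Sex.FEMALE)
            individuals += [father, mother]
        n_kids = int(rng.choice(sizes, p=probs))
        for _ in range(n_kids):
            sex = Sex.FEMALE if rng.random() < spec.girl_fraction else Sex.MALE
            individuals.append(
                Individual(new_id(), fam, father.individual_id,
                           mother.individual_id, sex)
            )
        prev_couple = (fam, father.individual_id, mother.individual_id)
    return Pedigree(individuals)


def generate_covariates(ped: Pedigree, spec: CohortSpec, rng=None) -> pd.DataFrame:
    """Ages (uniform over the study range) and sex for the study children."""
    rng = _rng(rng)
    children = ped.leaves()
    lo, hi = spec.age_range
    return pd.DataFrame(
        {
            "id": children,
            "age": np.round(rng.uniform(lo, hi, size=len(children)), 1),
            "sex": [int(ped[c].sex) for c in children],
        }
    )


def _trait_sqrt(corr: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(corr)
    if w.min() < -1e-8:
        raise ValueError("trait covariance block is not positive semi-definite")
    return V * np.sqrt(np.clip(w, 0.0, None))


def generate_phenotypes(
    ped: Pedigree,
    traits: list[TraitGenSpec],
    corr: CorrelationStructure | None = None,
    rng=None,
    covariates: pd.DataFrame | None = None,
    spec: CohortSpec | None = None,
    kinship: KinshipMatrix | None = None,
    return_latent: bool = False,
):
    """Draw multivariate phenotypes for the study children of a pedigree.

    Genetic effects are drawn per extended-family block from
    MVN(0, G (x) 2*Phi) via matrix square roots, environmental effects iid
    from MVN(0, E); the unit-variance latent is their sum. Observed traits
    add age/sex effects on the latent scale and apply the declared transform.
    Returns the phenotype table (id, age, sex, one column per trait);
    with ``return_latent=True`` also the latent table.
    """
    rng = _rng(rng)
    corr = corr if corr is not None else CorrelationStructure.independent(
        [t.name for t in traits]
    )
    if [t.name for t in traits] != corr.names:
        raise ValueError("trait order must match the correlation structure")
    h2 = np.array([t.h2 for t in traits])
    implied = corr.implied_phenotypic(h2)
    if np.linalg.eigvalsh(implied).min() < -1e-8:
        raise ValueError(
            "implied phenotypic correlation matrix is not positive semi-definite"
        )

    kin = kinship if kinship is not None else compute_kinship(ped)
    children = ped.leaves()
    kin_c = kin.subset(children)
    n, k = len(children), len(traits)

    dh = np.sqrt(h2)
    de = np.sqrt(1.0 - h2)
    G = np.outer(dh, dh) * corr.rho_g
    E = np.outer(de, de) * corr.rho_e
    Bg = _trait_sqrt(G)  # Bg @ Bg.T = G
    Be = _trait_sqrt(E)

    latent = np.empty((n, k))
    K = 2.0 * kin_c.values
    for block in kin_c.family_blocks():
        w, U = np.linalg.eigh(K[np.ix_(block, block)])
        A = U * np.sqrt(np.clip(w, 0.0, None))  # A @ A.T = K_block
        Z = rng.standard_normal((len(block), k))
        latent[block] = A @ Z @ Bg.T
    latent += rng.standard_normal((n, k)) @ Be.T

    if covariates is None:
        covariates = generate_covariates(
            ped, spec if spec is not None else CohortSpec(), rng
        )
    cov = covariates.set_index("id").loc[children]
    age_c = cov["age"].to_numpy(dtype=float) - 11.5
    girl = (cov["sex"].to_numpy(dtype=float) == int(Sex.FEMALE)).astype(float)

    out = {"id": children, "age": cov["age"].to_numpy(), "sex": cov["sex"].to_numpy()}
    for j, t in enumerate(traits):
        zed = latent[:, j] + t.age_beta * age_c + t.sex_beta * girl
        if t.transform == "identity":
            out[t.name] = t.mean + t.sd * zed
        else:  # log-normal with matching observed mean/sd
            s2 = np.log1p((t.sd / t.mean) ** 2)
            out[t.name] = t.mean * np.exp(np.sqrt(s2) * zed - s2 / 2.0)
    df = pd.DataFrame(out)
    if return_latent:
        lat = pd.DataFrame(latent, columns=[t.name for t in traits])
        lat.insert(0, "id", children)
        return df, lat
    return df


#: OGTT timepoints (minutes) and post-load excursion shapes
OGTT_TIMEPOINTS = (0, 30, 60, 90, 120)
_GLUCOSE_SHAPE = {30: 0.35, 60: 0.28, 90: 0.15, 120: 0.05}
_INSULIN_SHAPE = {30: 3.5, 60: 2.8, 90: 1.6, 120: 0.7}

#: fasting calibration targets (observed means/SDs of the study population)
FASTING_GLUCOSE_MEAN, FASTING_GLUCOSE_SD = 89.5, 7.5
FASTING_INSULIN_MEAN, FASTING_INSULIN_SD = 13.6, 9.4


def generate_ogtt(
    latent,
    rng=None,
    timepoints=OGTT_TIMEPOINTS,
    noise: float = 1.0,
) -> pd.DataFrame:
    """Glucose/insulin OGTT curves monotone in an insulin-resistance latent.

    ``latent`` is a standard-normal insulin-resistance score per child (a
    pandas Series indexed by id, or an array). Fasting glucose is log-normal
    with mean 89.5 and SD ~7.5 mg/dl; fasting insulin log-normal with mean
    13.6 and SD ~9.4 uIU/ml. Post-load excursions scale multiplicatively
    with the latent, so with ``noise=0`` every curve value, and hence the
    Matsuda ISI (inversely), is strictly monotone in the latent.
    """
    rng = _rng(rng)
    if isinstance(latent, pd.Series):
        ids = latent.index.to_numpy()
        lat = latent.to_numpy(dtype=float)
    else:
        lat = np.asarray(latent, dtype=float)
        ids = np.arange(lat.size)
    n = lat.size

    sg = np.sqrt(np.log1p((FASTING_GLUCOSE_SD / FASTING_GLUCOSE_MEAN) ** 2))
    si = np.sqrt(np.log1p((FASTING_INSULIN_SD / FASTING_INSULIN_MEAN) ** 2))
    ug = 0.4 * lat + noise * np.sqrt(1 - 0.4**2) * rng.standard_normal(n)
    ui = 0.6 * lat + noise * np.sqrt(1 - 0.6**2) * rng.standard_normal(n)
    g0 = FASTING_GLUCOSE_MEAN * np.exp(sg * ug - sg * sg / 2.0)
    i0 = FASTING_INSULIN_MEAN * np.exp(si * ui - si * si / 2.0)

    out = {"id": ids, "glucose_0": g0, "insulin_0": i0}
    mg = np.exp(0.35 * lat + noise * 0.15 * rng.standard_normal(n))
    mi = np.exp(0.30 * lat + noise * 0.15 * rng.standard_normal(n))
    for t in timepoints:
        if t == 0:
            continue
        eg = noise * 0.04 * rng.standard_normal(n)
        ei = noise * 0.08 * rng.standard_normal(n)
        out[f"glucose_{t}"] = g0 * (1.0 + _GLUCOSE_SHAPE[t] * mg) * np.exp(eg)
        out[f"insulin_{t}"] = i0 * (1.0 + _INSULIN_SHAPE[t] * mi) * np.exp(ei)
    cols = ["id"] + [f"{q}_{t}" for t in timepoints for q in ("glucose", "insulin")]
    return pd.DataFrame(out)[cols]


@dataclass
class SyntheticCohort:
    """Pedigree plus generated phenotype table (and latents) for one cohort."""

    pedigree: Pedigree
    kinship: KinshipMatrix
    phenotypes: pd.DataFrame
    latents: pd.DataFrame


def simulate_cohort(
    spec: CohortSpec,
    traits: list[TraitGenSpec],
    corr: CorrelationStructure | None = None,
    seed: int | None = None,
    ogtt: bool = False,
    ir_source: str | None = None,
    carotenoid_effects: dict[str, float] | None = None,
) -> SyntheticCohort:
    """One-call cohort: pedigree, kinship, covariates and phenotypes.

    With ``ogtt=True`` an OGTT table is merged in, driven by the latent of
    ``ir_source`` (default: the first trait). ``carotenoid_effects`` maps a
    trait name to a saturating protective effect on the insulin-resistance
    latent (gamma * tanh of the z-scored carotenoid), the generative hook for
    the carotenoid x metabolic-index interaction surfaces.
    """
    rng = _rng(seed if seed is not None else spec.seed)
    ped = generate_pedigree(spec, rng)
    kin = compute_kinship(ped)
    pheno, lat = generate_phenotypes(
        ped, traits, corr, rng, spec=spec, kinship=kin, return_latent=True
    )
    if ogtt:
        source = ir_source or traits[0].name
        ir = lat.set_index("id")[source].copy()
        for name, gamma in (carotenoid_effects or {}).items():
            x = pheno.set_index("id")[name]
            xz = (x - x.mean()) / x.std()
            ir = ir - gamma * np.tanh(xz)
        curves = generate_ogtt(ir, rng)
        pheno = pheno.merge(curves, on="id")
    return SyntheticCohort(pedigree=ped, kinship=kin, phenotypes=pheno, latents=lat)
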