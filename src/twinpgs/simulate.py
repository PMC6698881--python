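"""Forward simulation of dizygotic (DZ) twin cohorts with a known causal structure.

The generator produces family clusters — two parents and two DZ co-twins —
at unlinked biallelic loci, together with a polygenic score, an outcome, and
a family socio-economic status (SES) composite, so that every downstream
estimator (within/between decomposition, bootstrap tests, quantile analysis,
GRM sensitivity model) can be checked by parameter recovery.

Generative model per family j with co-twins i = 1, 2:

    outcome_ij = beta_direct * z_ij + beta_nurture * zmid_j
                 + c_shared * C_j + delta_{s(j)} + e_ij
    ses_j      = lambda_ses * zmid_j + nu_ses * C_j + sigma_ses * u_j

where z_ij is the twin's standardized polygenic score, zmid_j the
standardized mid-parent score (the route for passive gene-environment
correlation / genetic nurture: parents shape the family environment in
proportion to their own genotypes), C_j ~ N(0,1) a shared-environment draw,
delta_s a per-subpopulation environmental offset, and e_ij ~ N(0, sigma_e^2).

Population structure follows the Balding-Nichols model: subpopulation allele
frequencies are Beta-distributed around a common base frequency with
divergence ``fst``. Assortative mating pairs parents within subpopulation by
rank-matching a noisy proxy of their genetic value, calibrated so that the
realized mate correlation approximates ``r_mate``.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass
class SimulationConfig:
    """Full parameterization of the generative DZ-twin family model.

    Effect sizes are per standard deviation of the (standardized) polygenic
    scores; variance parameters are standard deviations of their respective
    terms, so with the defaults the outcome variance is close to 1.
    """

    n_families: int = 1000
    n_loci: int = 500
    freq_low: float = 0.1
    freq_high: float = 0.9
    beta_direct: float = 0.3
    beta_nurture: float = 0.0
    c_shared: float = 0.5
    sigma_e: float = 0.81
    r_mate: float = 0.0
    n_subpops: int = 1
    fst: float = 0.0
    strat_shift: float = 0.0
    lambda_ses: float = 0.5
    nu_ses: float = 0.5
    sigma_ses: float = 0.7071
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if not (0.0 < self.freq_low <= self.freq_high < 1.0):
            raise ConfigError("require 0 < freq_low <= freq_high < 1")
        for name in ("c_shared", "sigma_e", "strat_shift", "sigma_ses"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0.0 <= self.r_mate < 1.0):
            raise ConfigError("r_mate must be in [0, 1)")
        if not (0.0 <= self.fst < 1.0):
            raise ConfigError("fst must be in [0, 1)")
        if self.n_subpops < 1:
            raise ConfigError("n_subpops must be >= 1")
        if self.n_subpops > self.n_families:
            raise ConfigError("n_subpops cannot exceed n_families")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config fields: {sorted(extra)}")
        return cls(**d)


@dataclass
class ParentPool:
    """Parental genotypes (rows families, columns loci) with subpopulation labels."""

    fathers: np.ndarray
    mothers: np.ndarray
    subpop: np.ndarray
    base_freqs: np.ndarray
    subpop_freqs: np.ndarray  # (n_subpops, n_loci)


@dataclass
class SimulatedCohort:
    """A simulated cohort: long-format table plus the underlying arrays.

    ``table`` has two rows per family (member 1 and 2) and carries the
    analysis columns (gps, outcome, ses, sex) together with oracle columns
    prefixed ``true_`` holding generative quantities for recovery tests.
    Genotype arrays are ordered by family and can feed the scoring and GRM
    modules directly.
    """

    config: SimulationConfig
    table: pd.DataFrame
    weights: np.ndarray
    base_freqs: np.ndarray
    subpop_freqs: np.ndarray
    subpop: np.ndarray
    father_genotypes: np.ndarray
    mother_genotypes: np.ndarray
    twin1_genotypes: np.ndarray
    twin2_genotypes: np.ndarray
    father_scores: np.ndarray
    mother_scores: np.ndarray
    twin_scores_raw: np.ndarray  # (n_families, 2), unstandardized

    @property
    def twin_genotypes(self) -> np.ndarray:
        """Twin dosages interleaved to match ``table`` row order (2n, L)."""
        n, L = self.twin1_genotypes.shape
        out = np.empty((2 * n, L), dtype=self.twin1_genotypes.dtype)
        out[0::2] = self.twin1_genotypes
        out[1::2] = self.twin2_genotypes
        return out

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def provenance(self) -> dict:
        return {"config": self.config.to_dict(), "seed": self.config.seed}

    def provenance_json(self) -> str:
        return json.dumps(self.provenance(), indent=2, sort_keys=True)


def _stage_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _subpop_labels(n_families: int, n_subpops: int) -> np.ndarray:
    sizes = np.full(n_subpops, n_families // n_subpops)
    sizes[: n_families % n_subpops] += 1
    return np.repeat(np.arange(n_subpops), sizes)


def _balding_nichols(base: np.ndarray, fst: float, n_subpops: int,
                     rng: np.random.Generator) -> np.ndarray:
    if fst == 0.0:
        return np.tile(base, (n_subpops, 1))
    a = base * (1.0 - fst) / fst
    b = (1.0 - base) * (1.0 - fst) / fst
    freqs = rng.beta(a, b, size=(n_subpops, base.size))
    return np.clip(freqs, 1e-6, 1.0 - 1e-6)


def simulate_parents(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> ParentPool:
    """Draw parental genotypes per subpopulation.

    Subpopulation allele frequencies follow a Balding-Nichols Beta
    distribution around uniform base frequencies when ``fst > 0``; genotypes
    are binomial(2, p) per locus (Hardy-Weinberg within subpopulation).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    base = rng.uniform(config.freq_low, config.freq_high, config.n_loci)
    sub_freqs = _balding_nichols(base, config.fst, config.n_subpops, rng)
    labels = _subpop_labels(config.n_families, config.n_subpops)
    p = sub_freqs[labels]  # (n_families, n_loci)
    fathers = rng.binomial(2, p).astype(np.int8)
    mothers = rng.binomial(2, p).astype(np.int8)
    return ParentPool(fathers, mothers, labels, base, sub_freqs)


def draw_weights(base_freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-locus additive effect weights.

    Drawn N(0, 1/(2 L pbar (1-pbar))) so that the raw weighted allele sum has
    variance near 1, which keeps standardization mild and effect sizes per-SD.
    """
    pbar = float(np.mean(base_freqs))
    L = base_freqs.size
    sd = np.sqrt(1.0 / (2.0 * L * pbar * (1.0 - pbar)))
    return rng.normal(0.0, sd, L)


def mate_assortatively(father_values: np.ndarray, mother_values: np.ndarray,
                       subpop: np.ndarray, r_mate: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Pair fathers with mothers within subpopulation; returns mother indices.

    Each sex receives a noisy proxy u = a*z + sqrt(1-a^2)*e of its
    standardized genetic value z, with reliability a = sqrt(r_mate); mates
    are matched by proxy rank within subpopulation, so the realized mate
    correlation on z approximates a^2 = r_mate. ``r_mate = 0`` degenerates to
    uniformly random pairing.
    """
    if not (0.0 <= r_mate < 1.0):
        raise ConfigError("r_mate must be in [0, 1)")
    father_values = np.asarray(father_values, dtype=float)
    mother_values = np.asarray(mother_values, dtype=float)
    if father_values.shape != mother_values.shape:
        raise ConfigError("equal numbers of fathers and mothers required")
    subpop = np.asarray(subpop)
    out = np.empty(father_values.size, dtype=np.intp)
    a = np.sqrt(r_mate)
    for s in np.unique(subpop):
        idx = np.flatnonzero(subpop == s)
        if r_mate == 0.0:
            out[idx] = idx[rng.permutation(idx.size)]
            continue
        fz = _standardize(father_values[idx])
        mz = _standardize(mother_values[idx])
        uf = a * fz + np.sqrt(1.0 - r_mate) * rng.normal(size=idx.size)
        um = a * mz + np.sqrt(1.0 - r_mate) * rng.normal(size=idx.size)
        pair = np.empty(idx.size, dtype=np.intp)
        pair[np.argsort(uf, kind="stable")] = idx[np.argsort(um, kind="stable")]
        out[idx] = pair
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1) if x.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - np.mean(x)) / sd


def transmit(father_genotypes: np.ndarray, mother_genotypes: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One meiosis per parent: offspring effect-allele dosage per locus.

    A homozygote transmits deterministically; a heterozygote transmits the
    effect allele with probability 1/2. Loci are unlinked.
    """
    f = np.asarray(father_genotypes)
    m = np.asarray(mother_genotypes)
    for g, who in ((f, "father"), (m, "mother")):
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError(f"{who} dosages must be in {{0, 1, 2}}")
    return (_gamete(f, rng) + _gamete(m, rng)).astype(np.int8)


def _gamete(g: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    fixed = (g == 2).astype(np.int8)
    coin = (rng.random(g.shape) < 0.5).astype(np.int8)
    return np.where(g == 1, coin, fixed)


def mendelian_consistent(father: np.ndarray, mother: np.ndarray,
                         child: np.ndarray) -> np.ndarray:
    """Boolean mask: child dosage achievable from the two parental dosages."""
    f, m, c = (np.asarray(a) for a in (father, mother, child))
    lo = (f == 2).astype(int) + (m == 2).astype(int)
    hi = (f > 0).astype(int) + (m > 0).astype(int)
    return (c >= lo) & (c <= hi)


def simulate_phenotypes(twin_z: np.ndarray, midparent_z: np.ndarray,
                        subpop: np.ndarray, config: SimulationConfig,
                        rng: np.random.Generator):
    """Outcomes and the family SES composite given standardized scores.

    Returns ``(outcomes (n,2), ses (n,), shared_env (n,), subpop_shift (n,))``.
    Co-twins share the shared-environment draw, the subpopulation offset and
    the family SES.
    """
    n = midparent_z.size
    C = rng.normal(size=n)
    delta = rng.normal(0.0, config.strat_shift, config.n_subpops) \
        if config.strat_shift > 0 else np.zeros(config.n_subpops)
    shift = delta[subpop]
    fam = (config.beta_nurture * midparent_z + config.c_shared * C + shift)
    eps = rng.normal(0.0, config.sigma_e, size=(n, 2))
    outcomes = config.beta_direct * twin_z + fam[:, None] + eps
    u = rng.normal(size=n)
    ses = (config.lambda_ses * midparent_z + config.nu_ses * C
           + config.sigma_ses * u)
    return outcomes, ses, C, shift


def generate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the full generative pipeline and assemble the long-format table.

    Stages: parents -> assortative pairing -> two independent meioses (the
    DZ co-twins) -> polygenic scoring -> phenotypes. All stage seeds derive
    deterministically from ``config.seed``; identical configs give
    bit-identical cohorts.
    """
    r_weights, r_parents, r_mating, r_meio1, r_meio2, r_pheno, r_misc = \
        _stage_rngs(config.seed, 7)
    pool = simulate_parents(config, r_parents)
    w = draw_weights(pool.base_freqs, r_weights)

    father_scores = pool.fathers @ w
    mother_scores = pool.mothers @ w
    mother_idx = mate_assortatively(father_scores, mother_scores, pool.subpop,
                                    config.r_mate, r_mating)
    mothers = pool.mothers[mother_idx]
    mother_scores = mother_scores[mother_idx]

    twin1 = transmit(pool.fathers, mothers, r_meio1)
    twin2 = transmit(pool.fathers, mothers, r_meio2)

    raw = np.column_stack([twin1 @ w, twin2 @ w])
    mu, sd = raw.mean(), raw.std(ddof=1)
    twin_z = (raw - mu) / sd
    mid_raw = 0.5 * (father_scores + mother_scores)
    midparent_z = _standardize(mid_raw)

    outcomes, ses, shared_env, shift = simulate_phenotypes(
        twin_z, midparent_z, pool.subpop, config, r_pheno)
    n = config.n_families
    sex = r_misc.integers(0, 2, size=(n, 2))

    fam_ids = np.arange(n)
    table = pd.DataFrame({
        "family_id": np.repeat(fam_ids, 2),
        "member": np.tile([1, 2], n),
        "iid": [f"{f}_{m}" for f in fam_ids for m in (1, 2)],
        "subpop": np.repeat(pool.subpop, 2),
        "sex": sex.ravel(),
        "gps": twin_z.ravel(),
        "outcome": outcomes.ravel(),
        "ses": np.repeat(ses, 2),
        "true_score": twin_z.ravel(),
        "true_midparent": np.repeat(midparent_z, 2),
        "true_shared_env": np.repeat(shared_env, 2),
        "true_subpop_shift": np.repeat(shift, 2),
    })
    return SimulatedCohort(
        config=config, table=table, weights=w, base_freqs=pool.base_freqs,
        subpop_freqs=pool.subpop_freqs, subpop=pool.subpop,
        father_genotypes=pool.fathers, mother_genotypes=mothers,
        twin1_genotypes=twin1, twin2_genotypes=twin2,
        father_scores=father_scores, mother_scores=mother_scores,
        twin_scores_raw=raw)
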