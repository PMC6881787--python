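"""Synthetic genotype x strain trials with known generative structure.

Each experimental unit's shoot dry weight follows the AMMI generative
model on the plot level::

    sdw = mu + alpha_i + beta_j + sum_k lambda_k xi_ik eta_kj + rep_b + eps

with strain effects alpha, genotype effects beta, an exactly
double-centered rank-t multiplicative interaction built from orthonormal
score vectors, a Gaussian replicate (block) effect and Gaussian plot
noise.  Negative controls receive ``mu + beta_j - inoculation_benefit``
(no strain term, no interaction); positive (N-fed) controls an elevated
constant mean.  Binary nodulation and fixation phenotypes are drawn from a
logistic link in the latent strain effectiveness ``alpha_i + interaction``,
so ineffective strains produce the nod+/fix- pattern; nodule counts are
Poisson given nodulation, and shoot %N (when measured) increases with
effectiveness so that Ndfa is positive in expectation for effective
strains.

Randomness uses one root seed; every unit draws from its own child stream
keyed by (genotype, treatment, replicate) labels, so subsetting a design
leaves the remaining units' draws untouched.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .anova import FactorialAnova
from .ammi import AmmiModel
from .design import (
    BEAN_GENOTYPES,
    NEGATIVE_CONTROL,
    POSITIVE_CONTROL,
    TrialDesign,
    jar_design,
    pot_design,
)

__all__ = [
    "SimulationConfig",
    "NullBatchResult",
    "make_interaction_scores",
    "simulate_trial",
    "simulate_null_batch",
    "jar_config",
    "pot_config",
]

# stream tags: 0 interaction scores, 1 replicate effects, 2 units, 3 batch runs
_TAG_SCORES, _TAG_REPS, _TAG_UNIT, _TAG_BATCH = 0, 1, 2, 3


def _unit_key(genotype: str, treatment: str) -> int:
    digest = hashlib.blake2b(f"{genotype}|{treatment}".encode(), digest_size=8)
    return int.from_bytes(digest.digest(), "big")


@dataclass(frozen=True)
class SimulationConfig:
    """Complete generative description of one synthetic trial.

    Effect vectors are keyed by label and must each sum to zero;
    ``singular_values`` has length ``interaction_rank`` and is
    non-increasing.  All default magnitudes are in grams on the shoot
    dry-weight scale.
    """

    design: TrialDesign
    grand_mean: float = 2.0
    strain_effects: Mapping[str, float] = field(default_factory=dict)
    genotype_effects: Mapping[str, float] = field(default_factory=dict)
    interaction_rank: int = 2
    singular_values: tuple[float, ...] = (1.5, 0.8)
    rep_effect_sd: float = 0.1
    noise_sd: float = 0.25
    nod_base_prob: float = 0.9
    fix_link_slope: float = 4.0
    seed: int = 0
    inoculation_benefit: float = 0.4
    pos_control_mean: float = 2.8
    nodule_mean: float = 25.0
    nodule_dw_per_nodule: float = 0.0025
    measure_n: bool = False
    n_base: float = 2.5
    n_gain: float = 1.0
    n_neg: float = 1.5
    n_pos: float = 3.5
    n_sd: float = 0.15

    def __post_init__(self) -> None:
        object.__setattr__(self, "singular_values", tuple(self.singular_values))
        d = self.design
        if set(self.strain_effects) != set(d.strains):
            raise ValueError("strain_effects keys must match the design's strains")
        if set(self.genotype_effects) != set(d.genotypes):
            raise ValueError("genotype_effects keys must match the design's genotypes")
        for name, eff in (("strain", self.strain_effects), ("genotype", self.genotype_effects)):
            if abs(sum(eff.values())) > 1e-8:
                raise ValueError(f"{name}_effects must sum to zero")
        if len(self.singular_values) != self.interaction_rank:
            raise ValueError("singular_values length must equal interaction_rank")
        if any(s < 0 for s in self.singular_values):
            raise ValueError("singular values must be >= 0")
        if list(self.singular_values) != sorted(self.singular_values, reverse=True):
            raise ValueError("singular values must be non-increasing")
        if self.rep_effect_sd < 0 or self.noise_sd <= 0:
            raise ValueError("rep_effect_sd must be >= 0 and noise_sd > 0")
        if not 0 <= self.nod_base_prob <= 1:
            raise ValueError("nod_base_prob must lie in [0, 1]")

    @property
    def is_null(self) -> bool:
        """True when the multiplicative interaction is identically zero."""
        return self.interaction_rank == 0 or all(s == 0 for s in self.singular_values)


def make_interaction_scores(
    g: int, e: int, t: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random orthonormal interaction scores (xi: g x t, eta: t x e).

    Columns of xi are orthonormal and orthogonal to the all-ones vector
    (likewise rows of eta), so any interaction built as
    ``sum_k lambda_k xi[:,k] eta[k,:]`` is exactly double-centered.
    Deterministic given the seed.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t > min(g - 1, e - 1):
        raise ValueError(f"t={t} exceeds min(g-1, e-1)={min(g - 1, e - 1)}")
    if t == 0:
        return np.zeros((g, 0)), np.zeros((0, e))
    rng = np.random.default_rng(np.random.SeedSequence((seed, _TAG_SCORES)))

    def centered_orthonormal(n: int) -> np.ndarray:
        M = rng.standard_normal((n, t))
        M -= M.mean(axis=0)
        Q, R = np.linalg.qr(M)
        Q = Q * np.sign(np.diag(R))  # deterministic orientation
        return Q

    xi = centered_orthonormal(g)
    eta = centered_orthonormal(e).T
    return xi, eta


def simulate_trial(config: SimulationConfig) -> pd.DataFrame:
    """Generate one trial as a canonical long-format table.

    Row order follows the design enumeration (genotype, treatment,
    replicate); the jar design yields exactly 500 rows, the pot design 200.
    """
    d = config.design
    strains = list(d.strains)
    genotypes = list(d.genotypes)
    s_idx = {s: i for i, s in enumerate(strains)}
    g_idx = {g: j for j, g in enumerate(genotypes)}

    xi, eta = make_interaction_scores(
        len(strains), len(genotypes), config.interaction_rank, config.seed
    )
    lam = np.asarray(config.singular_values, dtype=float)
    inter = (xi * lam) @ eta if config.interaction_rank else np.zeros(
        (len(strains), len(genotypes))
    )

    rng_rep = np.random.default_rng(np.random.SeedSequence((config.seed, _TAG_REPS)))
    rep_effects = rng_rep.normal(0.0, config.rep_effect_sd, d.replicates)

    nod_base_logit = logit(np.clip(config.nod_base_prob, 1e-9, 1 - 1e-9))
    rows = []
    for genotype, treatment, rep in d.iter_units():
        rng = np.random.default_rng(
            np.random.SeedSequence(
                (config.seed, _TAG_UNIT, _unit_key(genotype, treatment), rep)
            )
        )
        eps = rng.normal(0.0, config.noise_sd)
        base = config.grand_mean + config.genotype_effects[genotype]
        if treatment == NEGATIVE_CONTROL:
            mean = base - config.inoculation_benefit
            latent = None
        elif treatment == POSITIVE_CONTROL:
            mean = config.pos_control_mean
            latent = None
        else:
            i, j = s_idx[treatment], g_idx[genotype]
            latent = config.strain_effects[treatment] + inter[i, j]
            mean = base + latent

        sdw = max(mean + rep_effects[rep - 1] + eps, 0.0)

        if latent is None:
            nod = fix = 0
            nodule_number = 0
            nodule_dw = 0.0
            # keep the unit stream aligned across treatment kinds
            rng.random(2)
            rng.normal()
        else:
            p_nod = expit(nod_base_logit + config.fix_link_slope * latent)
            nod = int(rng.random() < p_nod)
            p_fix = expit(config.fix_link_slope * latent)
            fix = int(rng.random() < p_fix) if nod else 0
            z_ndw = rng.normal()
            if nod:
                rate = config.nodule_mean * max(1.0 + latent, 0.04)
                nodule_number = 1 + int(rng.poisson(rate))
                nodule_dw = max(
                    nodule_number * config.nodule_dw_per_nodule * (1.0 + 0.15 * z_ndw),
                    0.0,
                )
            else:
                nodule_number = 0
                nodule_dw = 0.0

        if config.measure_n:
            z_n = rng.normal()
            if treatment == NEGATIVE_CONTROL:
                n_percent = config.n_neg + config.n_sd * z_n
            elif treatment == POSITIVE_CONTROL:
                n_percent = config.n_pos + config.n_sd * z_n
            else:
                n_percent = config.n_base + config.n_gain * latent + config.n_sd * z_n
            n_percent = float(np.clip(n_percent, 0.1, 10.0))
        else:
            n_percent = np.nan

        rows.append(
            {
                "experiment": d.experiment,
                "genotype": genotype,
                "treatment": treatment,
                "replicate": rep,
                "nod": nod,
                "fix": fix,
                "nodule_number": nodule_number,
                "nodule_dw": nodule_dw,
                "sdw": sdw,
                "n_percent": n_percent,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class NullBatchResult:
    """P-values from repeated null simulations (no multiplicative interaction)."""

    interaction_pvalues: np.ndarray
    axis1_pvalues: np.ndarray
    n_runs: int

    def rejection_rate(self, alpha: float = 0.05, test: str = "interaction") -> float:
        """Fraction of runs with p < alpha for the chosen test."""
        p = self.interaction_pvalues if test == "interaction" else self.axis1_pvalues
        return float(np.mean(p < alpha))


def simulate_null_batch(
    config: SimulationConfig,
    n_runs: int,
    seed: int,
    response: str = "sdw",
) -> NullBatchResult:
    """Repeatedly simulate under additivity and test for interaction.

    ``config`` must carry a null interaction (all singular values zero);
    each run re-seeds the generator from a child of ``seed``, fits the
    factorial RCBD ANOVA and records the interaction-term p-value, plus
    the first-axis Gollob F-test p-value of the matching AMMI fit.
    """
    if not config.is_null:
        raise ValueError("simulate_null_batch requires all singular values = 0")
    p_int = np.empty(n_runs)
    p_ax1 = np.empty(n_runs)
    for run in range(n_runs):
        child = int(
            np.random.SeedSequence((seed, _TAG_BATCH, run)).generate_state(1)[0]
        ) & 0x7FFFFFFF
        records = simulate_trial(replace(config, seed=child))
        model = FactorialAnova(response=response).fit(records)
        p_int[run] = model.table_["Genotype x Strain"].p
        ammi = AmmiModel(replicates=model.n_replicates_).fit(model.cell_means_)
        axes = ammi.f_tests(model.residual_ms_, model.residual_df_)
        p_ax1[run] = axes.loc[0, "p"]
    return NullBatchResult(p_int, p_ax1, n_runs)


def _centered(values: Mapping[str, float]) -> dict[str, float]:
    mean = sum(values.values()) / len(values)
    return {k: v - mean for k, v in values.items()}


#: Latent effectiveness of the strain panel (grams SDW): the two R. tropici
#: strains strongly effective, mid-range type and local strains, the two
#: non-nodulating strains deleterious relative to the panel mean.
_STRAIN_EFFECTS_RAW = {
    "CFN42": 0.15,
    "CIAT899": 0.45,
    "ATCC14482": 0.10,
    "NAE136": 0.12,
    "NAE182": 0.08,
    "LMG6133": -0.65,
    "LMG23946": -0.65,
    "NAK91": 0.40,
}

_SEED_WEIGHT = {m.genotype: m.seed_weight_100 for m in BEAN_GENOTYPES}


def _genotype_effects(genotypes: Sequence[str]) -> dict[str, float]:
    # larger-seeded genotypes grow larger shoots: 0.012 g per g of 100-seed weight
    raw = {g: 0.012 * _SEED_WEIGHT[g] for g in genotypes}
    return _centered(raw)


def jar_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Default generative conditions for the 500-unit Leonard-jar screening."""
    design = overrides.pop("design", jar_design())
    params = dict(
        design=design,
        strain_effects=_centered(
            {s: _STRAIN_EFFECTS_RAW[s] for s in design.strains}
        ),
        genotype_effects=_genotype_effects(design.genotypes),
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def pot_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Default conditions for the 200-unit pot confirmation (with shoot %N).

    The pot experiment showed weaker genotype x strain interaction than the
    jars; the default singular values are halved accordingly.
    """
    design = overrides.pop("design", pot_design())
    params = dict(
        design=design,
        strain_effects=_centered(
            {s: _STRAIN_EFFECTS_RAW[s] for s in design.strains}
        ),
        genotype_effects=_genotype_effects(design.genotypes),
        singular_values=(0.75, 0.4),
        measure_n=True,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)
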