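"""Synthetic study-condition generators with known ground truth.

The generators emulate a four-group therapeutic-rescue design: a healthy
control group (CNT), a disease group (DM1, Muscleblind-like loss of
function), and one or more antisense-oligonucleotide treatment arms. Two
kinds of arms are distinguished:

* "blockmiR-like" arms occupy a single miRNA binding site on a target
  transcript and are modeled as perfectly on-target: they move disease-gene
  means a fraction ``recovery_fraction`` of the way back toward control.
* "antagomiR-like" arms silence a whole miRNA and additionally perturb an
  off-target gene set with log2 effects drawn from Normal(0, off_target_log2_sd).

Treated means interpolate *linearly* between disease and control means, so
the downstream linear-count % Recovery statistic has expectation exactly
100 * recovery_fraction for disease genes.

Counts are negative binomial with variance mu + dispersion * mu^2. Splicing
events are binomial reads at a true percent-spliced-in (PSI) per group.
Dose-response, qPCR, grip-strength and fiber-count records follow the
corresponding assay models. All draws are fixed by the config seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .countdata import CountMatrix
from .errors import ConfigError

DEFAULT_DOSES_NM = (2.0, 10.0, 50.0, 200.0, 1000.0, 5000.0)


# --------------------------------------------------------------------------
# expression counts
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class TreatmentArm:
    """One treatment arm of the design.

    recovery_fraction (rho) in [0, 2]: 0 leaves the disease signature in
    place, 1 restores control means exactly, >1 overshoots. Off-target
    perturbations are only allowed on antagomiR-like arms and are drawn per
    gene with probability ``off_target_rate`` from the pool selected by
    ``off_target_pool`` ("all" genes or only the "hard_targets").
    """

    name: str
    recovery_fraction: float = 0.8
    antagomir_like: bool = False
    off_target_rate: float = 0.0
    off_target_log2_sd: float = 1.0
    off_target_pool: str = "all"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the count simulation.

    Defaults reproduce the study conditions of the four-group design:
    2000 genes, 4 samples per group, 10% disease-affected genes with
    |log2 effect| in [1, 3], recovery fraction 0.8 for both arms, a global
    NB dispersion of 0.1, and log-normal baseline means (location 4,
    scale 1.5 on the natural-log scale) spanning lowly to highly
    expressed genes. 57 non-disease genes are designated "hard targets"
    (experimentally supported miRNA targets) for specificity reporting; the
    antagomiR-like arm derepresses each of them with probability 0.5 (log2
    effects of typical magnitude 2), emulating whole-miRNA silencing, while
    the blockmiR-like arm leaves them untouched.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 4
    control_group: str = "CNT"
    disease_group: str = "DM1"
    arms: tuple[TreatmentArm, ...] = (
        TreatmentArm("DM1_BlockmiR", recovery_fraction=0.8),
        TreatmentArm(
            "DM1_AntagomiR",
            recovery_fraction=0.8,
            antagomir_like=True,
            off_target_rate=0.5,
            off_target_log2_sd=2.0,
            off_target_pool="hard_targets",
        ),
    )
    frac_disease_genes: float = 0.1
    effect_log2_range: tuple[float, float] = (1.0, 3.0)
    n_hard_targets: int = 57
    baseline_mean_log_params: tuple[float, float] = (4.0, 1.5)
    dispersion: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_group <= 0:
            raise ConfigError("n_genes and n_samples_per_group must be positive")
        if not 0.0 <= self.frac_disease_genes < 1.0:
            raise ConfigError("frac_disease_genes must be in [0, 1)")
        low, high = self.effect_log2_range
        if low <= 0 or high < low:
            raise ConfigError(
                "effect_log2_range must satisfy 0 < low <= high so that disease "
                "means differ from control means for declared disease genes"
            )
        if self.n_hard_targets < 0:
            raise ConfigError("n_hard_targets must be >= 0")
        if self.baseline_mean_log_params[1] < 0:
            raise ConfigError("baseline log-scale must be >= 0")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        names = [self.control_group, self.disease_group] + [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise ConfigError("group names must be unique")
        for arm in self.arms:
            if not 0.0 <= arm.recovery_fraction <= 2.0:
                raise ConfigError(f"recovery fraction of arm {arm.name!r} outside [0, 2]")
            if not 0.0 <= arm.off_target_rate < 1.0:
                raise ConfigError(f"off_target_rate of arm {arm.name!r} outside [0, 1)")
            if arm.off_target_log2_sd <= 0:
                raise ConfigError(f"off_target_log2_sd of arm {arm.name!r} must be > 0")
            if arm.off_target_rate > 0 and not arm.antagomir_like:
                raise ConfigError(
                    f"arm {arm.name!r}: off-target perturbations are only applied "
                    "to antagomiR-like arms"
                )
            if arm.off_target_pool not in ("all", "hard_targets"):
                raise ConfigError("off_target_pool must be 'all' or 'hard_targets'")

    @property
    def group_order(self) -> list[str]:
        return [self.control_group, self.disease_group] + [a.name for a in self.arms]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float,
             n_samples: int) -> np.ndarray:
    """Draw (n_genes, n_samples) NB counts with variance mu + dispersion*mu^2."""
    shape = (len(mu), n_samples)
    if dispersion < 1e-12:
        return rng.poisson(np.broadcast_to(mu[:, None], shape))
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, np.broadcast_to(p[:, None], shape))


def generate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the count matrix and its ground truth.

    Returns the CountMatrix (all groups, ``n_samples_per_group`` each) and a
    truth table indexed by gene with columns ``is_disease_gene``,
    ``delta_log2``, ``is_hard_target`` and, per arm, ``off_target__<arm>``
    and ``true_recovery_pct__<arm>``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(n)])

    loc, scale = config.baseline_mean_log_params
    baseline = rng.lognormal(loc, scale, n)

    n_disease = int(round(config.frac_disease_genes * n))
    disease_idx = rng.choice(n, size=n_disease, replace=False) if n_disease else np.array([], int)
    is_disease = np.zeros(n, bool)
    is_disease[disease_idx] = True

    delta = np.zeros(n)
    if n_disease:
        low, high = config.effect_log2_range
        magnitude = rng.uniform(low, high, n_disease)
        sign = rng.choice([-1.0, 1.0], n_disease)
        delta[disease_idx] = sign * magnitude

    mu_control = baseline
    mu_disease = baseline * 2.0 ** delta

    non_disease = np.flatnonzero(~is_disease)
    n_ht = min(config.n_hard_targets, len(non_disease))
    hard_idx = rng.choice(non_disease, size=n_ht, replace=False) if n_ht else np.array([], int)
    is_hard = np.zeros(n, bool)
    is_hard[hard_idx] = True

    truth = pd.DataFrame(
        {
            "is_disease_gene": is_disease,
            "delta_log2": delta,
            "is_hard_target": is_hard,
        },
        index=pd.Index(gene_ids, name="gene"),
    )

    group_mu: dict[str, np.ndarray] = {
        config.control_group: mu_control,
        config.disease_group: mu_disease,
    }
    for arm in config.arms:
        mu = mu_disease + arm.recovery_fraction * (mu_control - mu_disease)
        off = np.zeros(n, bool)
        if arm.off_target_rate > 0:
            pool = hard_idx if arm.off_target_pool == "hard_targets" else np.arange(n)
            hit = pool[rng.random(len(pool)) < arm.off_target_rate]
            if len(hit):
                off[hit] = True
                eps = rng.normal(0.0, arm.off_target_log2_sd, len(hit))
                mu = mu.copy()
                mu[hit] = mu[hit] * 2.0 ** eps
        group_mu[arm.name] = mu
        truth[f"off_target__{arm.name}"] = off
        truth[f"true_recovery_pct__{arm.name}"] = np.where(
            is_disease, 100.0 * arm.recovery_fraction, 0.0
        )

    blocks, columns, labels = [], [], []
    for group in config.group_order:
        block = _nb_draw(rng, group_mu[group], config.dispersion, config.n_samples_per_group)
        blocks.append(block)
        columns.extend(f"{group}_s{j + 1}" for j in range(config.n_samples_per_group))
        labels.extend([group] * config.n_samples_per_group)

    counts = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(gene_ids, name="gene"), columns=columns
    )
    design = pd.Series(labels, index=pd.Index(columns, name="sample"), name="group")
    return CountMatrix(counts, design), truth


# --------------------------------------------------------------------------
# splicing events
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class SpliceSimConfig:
    """Parameters of the splicing-event simulation.

    ``n_affected`` events carry a disease PSI shift of ``dpsi_disease``
    percentage points; of those, ``n_reversed`` are moved back toward
    control by each arm's recovery fraction. Per-sample junction coverage
    is Poisson with mean ``coverage_mean``; inclusion reads are binomial
    at the true PSI.
    """

    n_events: int = 200
    n_affected: int = 30
    n_reversed: int = 25
    dpsi_disease: float = -40.0
    coverage_mean: float = 100.0
    control_psi_range: tuple[float, float] = (45.0, 95.0)
    n_samples_per_group: int = 4
    control_group: str = "CNT"
    disease_group: str = "DM1"
    arms: tuple[tuple[str, float], ...] = (("DM1_BlockmiR", 0.8), ("DM1_AntagomiR", 0.8))
    seed: int = 0

    def validate(self) -> None:
        if self.n_events <= 0 or self.n_samples_per_group <= 0:
            raise ConfigError("n_events and n_samples_per_group must be positive")
        if not 0 <= self.n_reversed <= self.n_affected <= self.n_events:
            raise ConfigError("need 0 <= n_reversed <= n_affected <= n_events")
        lo, hi = self.control_psi_range
        if not (0.0 <= lo <= hi <= 100.0):
            raise ConfigError("control_psi_range must lie within [0, 100]")
        if abs(self.dpsi_disease) > 100.0:
            raise ConfigError("dpsi_disease outside [-100, 100]")
        if self.coverage_mean <= 0:
            raise ConfigError("coverage_mean must be positive")
        for name, rho in self.arms:
            if not 0.0 <= rho <= 2.0:
                raise ConfigError(f"splicing recovery fraction of arm {name!r} outside [0, 2]")

    @property
    def group_order(self) -> list[str]:
        return [self.control_group, self.disease_group] + [name for name, _ in self.arms]


def generate_splice_events(
    config: SpliceSimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a long-format event table plus design and truth.

    Returns ``(events, design, truth)`` where ``events`` has columns
    event_id, gene, sample, inclusion, exclusion; ``design`` maps samples to
    groups; and ``truth`` holds per-event true PSI per group and the
    affected/reversed flags.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    event_ids = np.array([f"ev{i:04d}" for i in range(n)])
    genes = np.array([f"sg{i:04d}" for i in range(n)])

    lo, hi = config.control_psi_range
    psi_control = rng.uniform(lo, hi, n)
    affected_idx = rng.choice(n, size=config.n_affected, replace=False)
    reversed_idx = (
        rng.choice(affected_idx, size=config.n_reversed, replace=False)
        if config.n_reversed
        else np.array([], int)
    )
    is_affected = np.zeros(n, bool)
    is_affected[affected_idx] = True
    is_reversed = np.zeros(n, bool)
    is_reversed[reversed_idx] = True

    psi_disease = psi_control.copy()
    psi_disease[affected_idx] = np.clip(
        psi_control[affected_idx] + config.dpsi_disease, 0.0, 100.0
    )

    group_psi: dict[str, np.ndarray] = {
        config.control_group: psi_control,
        config.disease_group: psi_disease,
    }
    for name, rho in config.arms:
        psi = psi_disease.copy()
        psi[reversed_idx] = np.clip(
            psi_disease[reversed_idx]
            + rho * (psi_control[reversed_idx] - psi_disease[reversed_idx]),
            0.0,
            100.0,
        )
        group_psi[name] = psi

    rows = []
    labels: dict[str, str] = {}
    for group in config.group_order:
        psi = group_psi[group]
        for j in range(config.n_samples_per_group):
            sample = f"{group}_s{j + 1}"
            labels[sample] = group
            coverage = rng.poisson(config.coverage_mean, n)
            inclusion = rng.binomial(coverage, psi / 100.0)
            rows.append(
                pd.DataFrame(
                    {
                        "event_id": event_ids,
                        "gene": genes,
                        "sample": sample,
                        "inclusion": inclusion,
                        "exclusion": coverage - inclusion,
                    }
                )
            )
    events = pd.concat(rows, ignore_index=True)
    design = pd.Series(labels, name="group").rename_axis("sample")

    truth = pd.DataFrame(
        {"gene": genes, "is_affected": is_affected, "is_reversed": is_reversed},
        index=pd.Index(event_ids, name="event_id"),
    )
    for group in config.group_order:
        truth[f"psi_true_{group}"] = group_psi[group]
    return events, design, truth


# --------------------------------------------------------------------------
# assay records
# --------------------------------------------------------------------------
def generate_dose_response(
    true_tc50: float,
    hill: float = 1.0,
    noise_sd: float = 5.0,
    doses: Sequence[float] = DEFAULT_DOSES_NM,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a normalized inhibition curve (0-100%) at the given doses (nM).

    Responses follow a four-parameter logistic in log10 dose with bottom 0,
    top 100 and midpoint at ``true_tc50``, plus Normal(0, noise_sd) noise.
    """
    from .assays import four_param_logistic  # local import: one-way dependency

    if true_tc50 <= 0:
        raise ConfigError("true_tc50 must be positive")
    doses = np.asarray(doses, float)
    if np.any(doses <= 0):
        raise ConfigError("doses must be positive")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for dose in doses:
        mean = four_param_logistic(np.log10(dose), 0.0, 100.0, np.log10(true_tc50), hill)
        for rep in range(n_replicates):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            records.append((dose, rep + 1, mean + noise))
    return pd.DataFrame(records, columns=["dose_nm", "replicate", "response_pct"])


def generate_qpcr(
    group_log2_expression: Mapping[str, float],
    calibrator_group: str,
    n_samples: int = 3,
    n_technical: int = 3,
    biological_sd: float = 0.0,
    technical_sd: float = 0.2,
    base_ct_target: float = 24.0,
    base_ct_reference: float = 18.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table for the 2^-ddCt method.

    ``group_log2_expression`` gives each group's true log2 expression of the
    target relative to the calibrator group (which must map to 0). A 2-fold
    increase (log2 = 1) lowers the target Ct by one cycle.
    """
    if calibrator_group not in group_log2_expression:
        raise ConfigError("calibrator group missing from group_log2_expression")
    if n_samples <= 0 or n_technical <= 0:
        raise ConfigError("sample and replicate counts must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for group, log2_expr in group_log2_expression.items():
        for s in range(n_samples):
            sample = f"{group}_s{s + 1}"
            ct_t = base_ct_target - log2_expr + (rng.normal(0, biological_sd) if biological_sd else 0.0)
            ct_r = base_ct_reference + (rng.normal(0, biological_sd) if biological_sd else 0.0)
            for rep in range(n_technical):
                jt = rng.normal(0, technical_sd) if technical_sd else 0.0
                jr = rng.normal(0, technical_sd) if technical_sd else 0.0
                rows.append((group, sample, rep + 1, ct_t + jt, ct_r + jr))
    return pd.DataFrame(
        rows, columns=["group", "sample", "replicate", "ct_target", "ct_reference"]
    )


def generate_grip_records(
    n_mice: int = 5,
    pre_mean_g: float = 120.0,
    post_over_pre: float = 1.0,
    trial_sd_g: float = 10.0,
    weight_mean_g: float = 25.0,
    weight_sd_g: float = 2.0,
    n_trials: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate forelimb grip trials (grams) before and after treatment."""
    if n_mice <= 0 or n_trials <= 0:
        raise ConfigError("n_mice and n_trials must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(n_mice):
        weight = max(rng.normal(weight_mean_g, weight_sd_g), 1.0)
        pre = np.clip(rng.normal(pre_mean_g, trial_sd_g, n_trials), 0.0, None)
        post = np.clip(rng.normal(pre_mean_g * post_over_pre, trial_sd_g, n_trials), 0.0, None)
        rows.append([f"mouse{m + 1}", weight, *pre, *post])
    cols = (
        ["mouse", "body_weight_g"]
        + [f"pre_{t + 1}" for t in range(n_trials)]
        + [f"post_{t + 1}" for t in range(n_trials)]
    )
    return pd.DataFrame(rows, columns=cols)


def generate_fiber_counts(
    group_central_fraction: Mapping[str, float],
    n_mice: int = 5,
    mean_fibers: float = 500.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-mouse muscle-fiber counts with centrally located nuclei."""
    if n_mice <= 0 or mean_fibers <= 0:
        raise ConfigError("n_mice and mean_fibers must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for group, frac in group_central_fraction.items():
        if not 0.0 <= frac <= 1.0:
            raise ConfigError("central-nuclei fraction must be in [0, 1]")
        for m in range(n_mice):
            total = max(int(rng.poisson(mean_fibers)), 1)
            central = int(rng.binomial(total, frac))
            rows.append((group, f"{group}_m{m + 1}", total, central))
    return pd.DataFrame(rows, columns=["group", "mouse", "total_fibers", "central_nuclei"])
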