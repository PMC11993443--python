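"""Synthetic multi-dataset cohorts with the structure the analysis assumes.

The generator draws, per sample: an intrinsic subtype (LumA/LumB/HER2/Basal),
a latent immune-activation axis A ~ N(0, 1), gene-level expression
(subtype centroid on the subtype genes, a linear loading of A on the
signature and IGG genes, Gaussian noise, per-dataset mean shifts), a pCR
outcome from a logistic model on A and subtype, clinical covariates
correlated with A where the analysis expects signal, and exponential
survival times with proportional hazards for non-pCR and non-immune status.

Expression is Gaussian on a log2-like scale — the simplest structure
matching microarray conventions.  Probe-level redundancy and
platform-specific gene dropout are modelled by :func:`expand_probes` and
:func:`apply_platform` so the probe-aggregation and signature-adaptation
steps are exercisable end to end.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ClinicalTable
from .matrix import ExpressionMatrix, ProbeGeneMap
from .signature import IGG_GENES

__all__ = [
    "SyntheticConfig",
    "SUBTYPES",
    "subtype_genes",
    "signature_genes",
    "subtype_centroids",
    "simulate_cohort",
    "expand_probes",
    "apply_platform",
    "simulate_survival",
    "marginal_group_or",
]

SUBTYPES = ("LumA", "LumB", "HER2", "Basal")


def subtype_genes(count: int = 50) -> list[str]:
    """Subtype-discriminating gene universe (PAM50-like stand-in symbols)."""
    return [f"ST{i:02d}" for i in range(1, count + 1)]


def signature_genes(count: int = 19) -> list[str]:
    """Immune-signature gene symbols."""
    return [f"IM{i:02d}" for i in range(1, count + 1)]


def subtype_centroids(count: int = 50, amplitude: float = 2.0) -> pd.DataFrame:
    """Deterministic block centroids: each subtype is high on its own gene block."""
    genes = subtype_genes(count)
    profiles = pd.DataFrame(0.0, index=genes, columns=list(SUBTYPES))
    blocks = np.array_split(np.arange(count), len(SUBTYPES))
    for label, block in zip(SUBTYPES, blocks):
        profiles.iloc[block, profiles.columns.get_loc(label)] = amplitude
    return profiles


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort generator.

    Defaults emulate a mixed neoadjuvant cohort: luminal-dominant subtype
    mix, ~20% marginal pCR, and an immune effect strong enough that the
    signature group's pCR odds ratio lands in the published 4–6 range.
    """

    n_samples: int = 500
    n_datasets: int = 4
    #: LumA, LumB, HER2, Basal mixture weights
    subtype_proportions: tuple[float, float, float, float] = (0.35, 0.25, 0.20, 0.20)
    #: log-odds of pCR per unit immune activation A
    immune_effect_beta: float = 1.2
    baseline_pcr_logit: float = -1.8
    #: additive pCR log-odds shift per subtype (LumA, LumB, HER2, Basal)
    subtype_pcr_shifts: tuple[float, float, float, float] = (-1.0, -0.3, 0.4, 0.6)
    signature_gene_count: int = 19
    #: expression units per unit A on signature genes
    signature_loading: float = 1.0
    #: expression units per unit A on the IGG comparator genes
    igg_loading: float = 0.6
    probe_multiplicity: int = 1
    expression_noise_sd: float = 0.5
    #: sd of per-dataset, per-gene mean shifts (batch structure)
    dataset_shift_sd: float = 0.3
    #: scales how strongly TILs/HRD/TMB track the immune axis
    covariate_immune_corr: float = 1.0
    #: dataset id -> genes absent on that platform
    platform_dropout: Mapping[str, frozenset[str]] = dataclasses.field(default_factory=dict)
    #: monthly baseline hazard of distant recurrence
    baseline_hazard: float = 0.01
    hr_non_pcr: float = 2.5
    hr_non_immune: float = 1.8
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_datasets < 1:
            raise ValueError("n_samples and n_datasets must be positive")
        props = np.asarray(self.subtype_proportions, dtype=float)
        if props.size != 4 or (props < 0).any():
            raise ValueError("subtype_proportions must be 4 nonnegative reals")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"subtype_proportions must sum to 1, got {props.sum()!r}")
        if len(self.subtype_pcr_shifts) != 4:
            raise ValueError("subtype_pcr_shifts must have 4 entries")
        if self.signature_gene_count < 1:
            raise ValueError("signature_gene_count must be positive")
        if self.probe_multiplicity < 1:
            raise ValueError("probe_multiplicity must be >= 1")
        if self.expression_noise_sd < 0:
            raise ValueError(
                f"expression_noise_sd must be nonnegative, got {self.expression_noise_sd}"
            )
        if self.dataset_shift_sd < 0:
            raise ValueError("dataset_shift_sd must be nonnegative")
        if self.baseline_hazard <= 0 or self.hr_non_pcr <= 0 or self.hr_non_immune <= 0:
            raise ValueError("hazards and hazard ratios must be positive")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")

    def gene_universe(self) -> list[str]:
        return (
            subtype_genes()
            + signature_genes(self.signature_gene_count)
            + list(IGG_GENES)
        )


def _rng(config_seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, stage]))


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, pd.DataFrame]:
    """Generate one multi-dataset cohort.

    Returns the gene-level expression matrix, the clinical table (with pCR
    and covariates) and the per-sample truth record (dataset, subtype,
    immune activation A, pCR probability).
    """
    n = config.n_samples
    rng = _rng(config.seed, 0)

    sample_ids = [f"S{i:05d}" for i in range(1, n + 1)]
    datasets = np.array(
        [f"DS{(i * config.n_datasets) // n + 1}" for i in range(n)]
    )
    subtype_idx = rng.choice(4, size=n, p=np.asarray(config.subtype_proportions))
    subtypes = np.array(SUBTYPES)[subtype_idx]
    immune = rng.normal(size=n)  # latent activation A

    # --- expression -----------------------------------------------------
    genes = config.gene_universe()
    centroids = subtype_centroids()
    sig = signature_genes(config.signature_gene_count)
    expr = np.zeros((len(genes), n))
    gene_pos = {g: i for i, g in enumerate(genes)}
    st_rows = [gene_pos[g] for g in centroids.index]
    expr[st_rows, :] = centroids.to_numpy()[:, subtype_idx]
    sig_rows = [gene_pos[g] for g in sig]
    expr[sig_rows, :] += config.signature_loading * immune[None, :]
    igg_rows = [gene_pos[g] for g in IGG_GENES]
    expr[igg_rows, :] += config.igg_loading * immune[None, :]

    if config.dataset_shift_sd > 0:
        shift_rng = _rng(config.seed, 1)
        for ds in pd.unique(datasets):
            shift = shift_rng.normal(0.0, config.dataset_shift_sd, size=len(genes))
            expr[:, datasets == ds] += shift[:, None]
    if config.expression_noise_sd > 0:
        expr += rng.normal(0.0, config.expression_noise_sd, size=expr.shape)

    matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=genes, columns=sample_ids),
        feature_kind="gene",
        platform="synthetic",
    )

    # --- outcome ---------------------------------------------------------
    shifts = np.asarray(config.subtype_pcr_shifts)[subtype_idx]
    p_pcr = _logistic(config.baseline_pcr_logit + config.immune_effect_beta * immune + shifts)
    pcr = rng.random(n) < p_pcr

    # --- covariates -------------------------------------------------------
    cov_rng = _rng(config.seed, 2)
    corr = config.covariate_immune_corr
    proliferative = np.isin(subtypes, ("LumB", "HER2", "Basal")).astype(float)
    basal = (subtypes == "Basal").astype(float)
    her2_subtype = (subtypes == "HER2").astype(float)
    luminal = np.isin(subtypes, ("LumA", "LumB"))

    age = np.clip(cov_rng.normal(52, 10, n), 25, 85)
    ki67 = np.clip(cov_rng.normal(14, 8, n) + 18 * proliferative, 1, 95)
    tils = np.clip(cov_rng.normal(14, 7, n) + corr * 8 * immune, 0, 90)
    hrd = np.clip(cov_rng.normal(26, 10, n) + corr * 8 * immune + 14 * basal, 0, 100)
    tmb = np.clip(np.exp(cov_rng.normal(0.2, 0.45, n) + corr * 0.3 * immune), 0.05, 60)
    nlr = np.clip(cov_rng.normal(2.5, 0.8, n), 0.5, 12)
    plr = np.clip(cov_rng.normal(150, 40, n), 40, 450)
    rs = np.clip(8 + 0.6 * ki67 + cov_rng.normal(0, 8, n), 0, 100)

    er_prob = np.select(
        [subtypes == "LumA", subtypes == "LumB", subtypes == "HER2"], [0.95, 0.90, 0.35], 0.10
    )
    er_pos = cov_rng.random(n) < er_prob
    pgr_pos = cov_rng.random(n) < np.where(er_pos, 0.80, 0.10)
    her2_pos = cov_rng.random(n) < np.where(her2_subtype > 0, 0.85, 0.08)
    del luminal  # receptor status is the observable; subtype stays latent

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "dataset": datasets,
                "er": np.where(er_pos, "positive", "negative"),
                "pgr": np.where(pgr_pos, "positive", "negative"),
                "her2": np.where(her2_pos, "positive", "negative"),
                "anti_her2": pd.array(her2_pos, dtype="boolean"),
                "pcr": pd.array(pcr, dtype="boolean"),
                "age": age,
                "ki67": ki67,
                "tils": tils,
                "hrd": hrd,
                "tmb": tmb,
                "nlr": nlr,
                "plr": plr,
                "rs": rs,
            }
        )
    )
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "dataset": datasets,
            "subtype": subtypes,
            "immune_activation": immune,
            "p_pcr": p_pcr,
        }
    )
    return matrix, clinical, truth


def expand_probes(
    gene_matrix: ExpressionMatrix,
    multiplicity: int | Mapping[str, int],
    seed: int,
    offset_sd: float = 0.2,
    noise_sd: float = 0.1,
) -> tuple[ExpressionMatrix, ProbeGeneMap]:
    """Emit probe-level redundancy: per gene, ``multiplicity`` probes equal to
    the gene value plus a fixed probe offset and per-cell noise.

    ``multiplicity`` may be a single integer or a per-gene mapping (any gene
    missing from the mapping gets one probe).
    """
    if isinstance(multiplicity, int):
        if multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        counts = {g: multiplicity for g in gene_matrix.features}
    else:
        counts = {g: int(multiplicity.get(g, 1)) for g in gene_matrix.features}
        if any(k < 1 for k in counts.values()):
            raise ValueError("every probe multiplicity must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    probe_ids = []
    mapping = {}
    for gene in gene_matrix.features:
        base = gene_matrix.data.loc[gene].to_numpy()
        for k in range(counts[gene]):
            offset = rng.normal(0.0, offset_sd) if offset_sd > 0 else 0.0
            noise = (
                rng.normal(0.0, noise_sd, size=base.size) if noise_sd > 0 else 0.0
            )
            probe = f"{gene}_p{k + 1}"
            probe_ids.append(probe)
            mapping[probe] = gene
            rows.append(base + offset + noise)
    frame = pd.DataFrame(np.vstack(rows), index=probe_ids, columns=gene_matrix.samples)
    probe_matrix = ExpressionMatrix(
        frame, feature_kind="probe", platform=gene_matrix.platform
    )
    return probe_matrix, ProbeGeneMap(mapping)


def apply_platform(matrix: ExpressionMatrix, dropout) -> ExpressionMatrix:
    """Remove platform-unsupported genes (e.g. 3 of 19 signature genes)."""
    dropout = set(dropout)
    unknown = dropout - set(matrix.features)
    if unknown:
        raise KeyError(f"dropout contains unknown feature ids: {sorted(unknown)[:5]}")
    if not dropout:
        return matrix
    kept = [f for f in matrix.features if f not in dropout]
    tag = f"{matrix.platform}|dropout={len(dropout)}" if matrix.platform else f"dropout={len(dropout)}"
    return matrix.replace(data=matrix.data.loc[kept], platform=tag)


def simulate_survival(
    clinical: ClinicalTable,
    truth: pd.DataFrame,
    config: SyntheticConfig,
) -> ClinicalTable:
    """Attach exponential event times with proportional hazards.

    hazard_i = baseline × hr_non_pcr^(1−pCR_i) × hr_non_immune^(1−immune_i),
    where immune_i is the true latent status A_i > 0.  A fraction
    ``censoring_rate`` of subjects is independently censored uniformly
    before their event time.
    """
    frame = clinical.data.copy()
    truth = truth.set_index("sample_id").loc[frame["sample_id"]]
    rng = _rng(config.seed, 3)
    pcr = frame["pcr"].fillna(False).to_numpy(dtype=bool)
    immune = (truth["immune_activation"] > 0).to_numpy()
    hazard = (
        config.baseline_hazard
        * config.hr_non_pcr ** (1 - pcr.astype(float))
        * config.hr_non_immune ** (1 - immune.astype(float))
    )
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(len(frame)) < config.censoring_rate
    observed = np.where(censored, rng.random(len(frame)) * event_time, event_time)
    frame["time"] = observed
    frame["event"] = pd.array(~censored, dtype="boolean")
    return ClinicalTable(frame)


def marginal_group_or(
    config: SyntheticConfig,
    model,
    n_mc: int = 1_000_000,
    seed: int = 12345,
    chunk: int = 200_000,
) -> float:
    """Monte-Carlo truth for the marginal pCR odds ratio of Gp-R vs Gp-NR.

    Simulates ``n_mc`` samples from ``config`` (in chunks), scores them with
    the given signature model, and returns ad/bc of the aggregated group ×
    pCR table.  Serves as the large-sample reference value for parameter-
    recovery checks.
    """
    counts = np.zeros(4, dtype=np.int64)  # a, b, c, d
    remaining = n_mc
    child_seeds = np.random.SeedSequence(seed).generate_state(max(1, -(-n_mc // chunk)))
    for i, sub_seed in enumerate(child_seeds):
        if remaining <= 0:
            break
        size = min(chunk, remaining)
        remaining -= size
        sub = dataclasses.replace(config, n_samples=size, seed=int(sub_seed % (2**31)))
        matrix, clinical, _ = simulate_cohort(sub)
        scores = model.score(matrix)
        gp_r = (scores.group == "Gp-R").to_numpy()
        pcr = clinical.data["pcr"].to_numpy(dtype=bool)
        counts[0] += int((gp_r & pcr).sum())
        counts[1] += int((gp_r & ~pcr).sum())
        counts[2] += int((~gp_r & pcr).sum())
        counts[3] += int((~gp_r & ~pcr).sum())
    a, b, c, d = counts
    return (a * d) / (b * c)
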