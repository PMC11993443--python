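"""Diagonal linear discriminant (DLDA) immune signature: training and scoring.

The immune score (IS) of a sample x is the diagonal linear discriminant

    IS(x) = sum_j w_j (x_j - m_j),   w_j = (mu1_j - mu0_j) / s_j^2,
                                      m_j = (mu1_j + mu0_j) / 2,

where mu1_j/mu0_j are the class means of feature j (class 1 = responders)
and s_j^2 the pooled within-class variance, floored at a small epsilon.
Equal class priors are assumed, so the decision threshold is 0: samples
with IS > 0 are called Gp-R (chemotherapy-sensitive), IS <= 0 Gp-NR.
A secondary stratum at IS <= -25 marks a low-sensitivity subgroup.

The module follows the model/results pattern: :class:`DLDASignature` is
built from training data, its :meth:`~DLDASignature.fit` returns a
:class:`DLDASignatureResults` that scores new cohorts, adapts itself to
platforms missing some signature genes, serialises to JSON and prints a
per-feature summary table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "DLDASignature",
    "DLDASignatureResults",
    "SampleScores",
    "train_dlda",
    "score",
    "adapt_signature",
    "concordance",
    "igg_score",
    "probe_sum_score",
    "ri_score",
    "IGG_GENES",
    "PDL1_PROBES",
    "PD1_PROBES",
]

logger = logging.getLogger(__name__)

#: 11-gene immunoglobulin/B-cell comparator signature (sum of z-scores).
IGG_GENES = (
    "CD27", "CD79A", "HLA-C", "IGJ", "IGKC", "IL2RG",
    "CXCL8", "LAX1", "NTN3", "PIM2", "TNFRSF17",
)
#: default probe ids for the PD-L1 two-probe sum and the single PD-1 probe
#: (Affymetrix HG-U133 Plus 2.0 identifiers).
PDL1_PROBES = ("223834_at", "227458_at")
PD1_PROBES = ("207634_at",)

#: IS cutoff for the secondary low-sensitivity stratum.
LOW_IS_CUTOFF = -25.0
#: RS cutoff for chemotherapy-indicated recurrence risk.
RS_CUTOFF = 25.0


# ---------------------------------------------------------------------------
# scores container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SampleScores:
    """Per-sample immune scores and the Gp-R / Gp-NR call.

    ``data`` has columns ``sample_id``, ``is_score``, ``group``
    (``Gp-R`` iff IS > threshold) and ``stratum`` (``IS>-25`` / ``IS<=-25``).
    """

    data: pd.DataFrame
    threshold: float = 0.0

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def is_score(self) -> pd.Series:
        return pd.Series(
            self.data["is_score"].to_numpy(), index=self.data["sample_id"], name="is_score"
        )

    @property
    def group(self) -> pd.Series:
        return pd.Series(
            self.data["group"].to_numpy(), index=self.data["sample_id"], name="group"
        )

    def __len__(self) -> int:
        return len(self.data)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _scores_frame(sample_ids: Sequence[str], is_values: np.ndarray, threshold: float) -> SampleScores:
    group = np.where(is_values > threshold, "Gp-R", "Gp-NR")
    stratum = np.where(is_values > LOW_IS_CUTOFF, "IS>-25", "IS<=-25")
    frame = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "is_score": is_values.astype(float),
            "group": group,
            "stratum": stratum,
        }
    )
    return SampleScores(frame, threshold=threshold)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class DLDASignature:
    """Diagonal LDA model of a binary response from expression features.

    Parameters
    ----------
    X : ExpressionMatrix
        Training expression, features × samples.
    labels : sequence of bool/int
        Binary response per training sample, aligned with ``X.samples``;
        class 1 is the responder (pCR) class.
    variance_floor : float
        Lower bound applied to every pooled within-class variance.
    """

    def __init__(self, X: ExpressionMatrix, labels, variance_floor: float = 1e-6):
        if variance_floor <= 0:
            raise ValueError("variance_floor must be positive")
        labels = np.asarray(labels)
        if labels.shape[0] != X.shape[1]:
            raise ValueError(
                f"labels length {labels.shape[0]} != number of samples {X.shape[1]}"
            )
        labels = labels.astype(bool)
        for cls in (True, False):
            if (labels == cls).sum() < 2:
                raise ValueError(
                    "DLDA training needs >=2 samples in each class "
                    f"(class {int(cls)} has {(labels == cls).sum()})"
                )
        if X.shape[0] < 2:
            raise ValueError("DLDA training needs >=2 features")
        self.X = X
        self.labels = labels
        self.variance_floor = float(variance_floor)

    def fit(self, training_id: str = "") -> "DLDASignatureResults":
        values = self.X.values()
        pos = values[:, self.labels]
        neg = values[:, ~self.labels]
        mu1 = pos.mean(axis=1)
        mu0 = neg.mean(axis=1)
        n1, n0 = pos.shape[1], neg.shape[1]
        # pooled within-class variance with n1+n0-2 denominator
        ss1 = ((pos - mu1[:, None]) ** 2).sum(axis=1)
        ss0 = ((neg - mu0[:, None]) ** 2).sum(axis=1)
        s2 = (ss1 + ss0) / (n1 + n0 - 2)
        s2 = np.maximum(s2, self.variance_floor)
        weights = (mu1 - mu0) / s2
        midpoints = (mu1 + mu0) / 2.0
        return DLDASignatureResults(
            features=list(self.X.features),
            weights=weights,
            midpoints=midpoints,
            variances=s2,
            threshold=0.0,
            metadata={
                "training_id": training_id,
                "n_class1": int(n1),
                "n_class0": int(n0),
                "variance_floor": self.variance_floor,
                "class_labels": ["non-pCR", "pCR"],
            },
        )


@dataclasses.dataclass
class DLDASignatureResults:
    """Fitted DLDA signature: per-feature weights, midpoints and threshold."""

    features: list[str]
    weights: np.ndarray
    midpoints: np.ndarray
    variances: np.ndarray
    threshold: float = 0.0
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.midpoints = np.asarray(self.midpoints, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if len(self.features) < 2:
            raise ValueError("signature needs >=2 features")
        if not (
            len(self.features) == self.weights.size == self.midpoints.size == self.variances.size
        ):
            raise ValueError("features, weights, midpoints, variances must align")
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite weights")
        if (self.variances <= 0).any():
            raise ValueError("variances must be positive")

    # -- scoring ---------------------------------------------------------
    def score(self, X: ExpressionMatrix) -> SampleScores:
        """Immune score IS(x) = Σ_j w_j (x_j − m_j) and group call per sample."""
        missing = [f for f in self.features if f not in X.data.index]
        if missing:
            raise KeyError(
                f"signature features missing from matrix: {missing[:10]} "
                "(adapt the signature to the available features first)"
            )
        values = X.data.loc[self.features].to_numpy(dtype=float)
        is_values = self.weights @ (values - self.midpoints[:, None])
        return _scores_frame(X.samples, is_values, self.threshold)

    # -- platform adaptation --------------------------------------------
    def adapt(
        self,
        available: Iterable[str],
        train_X: ExpressionMatrix,
        train_labels,
        min_features: int = 16,
    ) -> "DLDASignatureResults":
        """Refit the signature on the intersection with ``available`` features.

        Mirrors the cross-platform rule for the published 19-gene signature,
        where 16 of the 19 genes were supported on other array platforms and
        the discriminant coefficients were recalculated within the training
        set on those 16.
        """
        available = set(available)
        kept = [f for f in self.features if f in available]
        if len(kept) < min_features:
            raise ValueError(
                f"only {len(kept)} of {len(self.features)} signature features available; "
                f"at least {min_features} required (cross-platform precedent: 16 of 19 genes)"
            )
        dropped = [f for f in self.features if f not in available]
        refit = DLDASignature(
            train_X.subset(kept),
            train_labels,
            variance_floor=self.metadata.get("variance_floor", 1e-6),
        ).fit(training_id=self.metadata.get("training_id", ""))
        refit.metadata["adapted_from"] = len(self.features)
        refit.metadata["dropped_features"] = dropped
        if dropped:
            logger.info("adapt_signature: refit without %d features: %s", len(dropped), dropped)
        return refit

    # -- persistence -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "features": self.features,
            "weights": self.weights.tolist(),
            "midpoints": self.midpoints.tolist(),
            "variances": self.variances.tolist(),
            "threshold": self.threshold,
            "metadata": self.metadata,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2)
            handle.write("\n")

    @classmethod
    def from_json(cls, path) -> "DLDASignatureResults":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(
            features=list(payload["features"]),
            weights=np.asarray(payload["weights"], dtype=float),
            midpoints=np.asarray(payload["midpoints"], dtype=float),
            variances=np.asarray(payload["variances"], dtype=float),
            threshold=float(payload.get("threshold", 0.0)),
            metadata=dict(payload.get("metadata", {})),
        )

    def summary(self) -> str:
        """Plain-text per-feature table of weights, midpoints and variances."""
        lines = [
            "DLDA immune signature",
            f"  features: {len(self.features)}   threshold: {self.threshold:g}",
            f"  training: {self.metadata.get('training_id', '-')} "
            f"(n1={self.metadata.get('n_class1', '?')}, n0={self.metadata.get('n_class0', '?')})",
            "",
            f"  {'feature':<12}{'weight':>12}{'midpoint':>12}{'variance':>12}",
        ]
        for f, w, m, s2 in zip(self.features, self.weights, self.midpoints, self.variances):
            lines.append(f"  {f:<12}{w:>12.4f}{m:>12.4f}{s2:>12.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def train_dlda(X: ExpressionMatrix, labels, variance_floor: float = 1e-6) -> DLDASignatureResults:
    """Train a DLDA signature (functional wrapper around :class:`DLDASignature`)."""
    return DLDASignature(X, labels, variance_floor=variance_floor).fit()


def score(X: ExpressionMatrix, model: DLDASignatureResults) -> SampleScores:
    return model.score(X)


def adapt_signature(
    model: DLDASignatureResults,
    available: Iterable[str],
    train_X: ExpressionMatrix,
    train_labels,
    min_features: int = 16,
) -> DLDASignatureResults:
    return model.adapt(available, train_X, train_labels, min_features=min_features)


def concordance(scores_a: SampleScores, scores_b: SampleScores) -> tuple[float, int]:
    """Pearson r between two IS vectors plus the discordant group-call count."""
    ids_a, ids_b = set(scores_a.sample_ids), set(scores_b.sample_ids)
    if ids_a != ids_b:
        raise ValueError(
            f"score sets cover different samples ({len(ids_a ^ ids_b)} mismatched ids)"
        )
    a = scores_a.is_score
    b = scores_b.is_score.reindex(a.index)
    r = float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])
    discordant = int(
        (scores_a.group != scores_b.group.reindex(scores_a.group.index)).sum()
    )
    return r, discordant


def _sum_over_features(zX: ExpressionMatrix, wanted: Sequence[str], what: str) -> pd.Series:
    if not zX.zscaled:
        raise ValueError(f"{what} expects a z-scaled matrix (zscaled flag not set)")
    present = [g for g in wanted if g in zX.data.index]
    if not present:
        raise ValueError(f"none of the {what} features are present: {list(wanted)}")
    missing = [g for g in wanted if g not in present]
    if missing:
        warnings.warn(
            f"{what}: {len(missing)} of {len(wanted)} features absent, "
            f"summing over the remaining {len(present)} ({missing})",
            stacklevel=3,
        )
    total = zX.data.loc[present].sum(axis=0)
    total.index.name = "sample_id"
    return total.rename(what)


def igg_score(zX: ExpressionMatrix, genes: Sequence[str] = IGG_GENES) -> pd.Series:
    """Immunoglobulin/B-cell comparator score: per-sample sum of 11 gene z-scores."""
    return _sum_over_features(zX, genes, "igg_score")


def probe_sum_score(zX: ExpressionMatrix, probes: Sequence[str] = PDL1_PROBES) -> pd.Series:
    """Per-sample sum of z-scores over listed probes (defaults: PD-L1 pair)."""
    return _sum_over_features(zX, probes, "probe_sum_score")


RI_QUADRANTS = (
    "IS>-25 & RS>25",
    "IS>-25 & RS<=25",
    "IS<=-25 & RS<=25",
    "IS<=-25 & RS>25",
)


def ri_score(
    rs: pd.Series,
    is_score: pd.Series,
    rs_weight: float = 1.0,
    is_weight: float = 1.0,
) -> pd.DataFrame:
    """Combined recurrence + immune score (RI = RS + IS) and cutoff quadrant.

    Quadrants use strict cutoffs IS > −25 and RS > 25.  Samples missing
    either input are excluded with a logged count.
    """
    paired = pd.DataFrame({"rs": rs, "is_score": is_score})
    n_before = len(paired)
    paired = paired.dropna()
    excluded = n_before - len(paired)
    if excluded:
        logger.info("ri_score: excluded %d samples missing RS or IS", excluded)
    if paired.empty:
        raise ValueError("no samples with both RS and IS")
    ri = rs_weight * paired["rs"] + is_weight * paired["is_score"]
    is_high = paired["is_score"] > LOW_IS_CUTOFF
    rs_high = paired["rs"] > RS_CUTOFF
    quadrant = np.select(
        [
            is_high & rs_high,
            is_high & ~rs_high,
            ~is_high & ~rs_high,
            ~is_high & rs_high,
        ],
        RI_QUADRANTS,
        default="",  # conditions are exhaustive
    )
    out = pd.DataFrame(
        {"rs": paired["rs"], "is_score": paired["is_score"], "ri": ri, "quadrant": quadrant},
        index=paired.index,
    )
    out.index.name = "sample_id"
    return out
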