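"""Fraction-of-risk-genotype classifier with ROC cutoffs and LOOCV.

A sample's risk score is the fraction of its *called* signature loci that
carry the designated risk genotype: in validation mode the risk genotype
is the case-predominant genotype at each locus; in discovery mode the
score counts loci whose call differs from the control modal genotype.
A sample scoring at or above the cutoff is classified "at-risk".

The user-facing entry point follows the Model/Results convention:
``MicrosatelliteRiskModel(matrix).fit()`` screens the loci, builds the
signature, sweeps the ROC, picks the accuracy-optimal cutoff, and returns
a :class:`RiskModelResults` carrying the estimates, the diagnostics, a
``summary()`` table, ``predict()`` and ``loocv()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genotyper import Genotype, GenotypeMatrix
from .screen import LocusStats, locus_odds_ratio, select_informative_loci

__all__ = [
    "ClassifierModel",
    "RocResult",
    "ConfusionMatrix",
    "score_sample",
    "roc_auc",
    "optimal_cutoff",
    "evaluate",
    "loocv",
    "LoocvResult",
    "MicrosatelliteRiskModel",
    "RiskModelResults",
]


@dataclass
class ClassifierModel:
    """Signature loci, their reference genotypes, and a score cutoff.

    ``signature`` maps each locus to the genotype the score is counted
    against: the risk (case-predominant) genotype in validation mode, the
    control modal genotype in discovery mode (where carrying *any other*
    genotype contributes to the score).
    """

    signature: list[tuple[str, Genotype]]
    cutoff: float
    mode: str = "validation"

    def __post_init__(self):
        if not self.signature:
            raise ValueError("signature must be non-empty")
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError("cutoff must lie in [0, 1]")
        if self.mode not in ("discovery", "validation"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def save(self, path) -> None:
        payload = {
            "format": "mstrisk-classifier",
            "version": 1,
            "mode": self.mode,
            "cutoff": self.cutoff,
            "signature": [
                {"locus_id": lid, "a1": g.a1, "a2": g.a2} for lid, g in self.signature
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "mstrisk-classifier":
            raise ValueError(f"{path}: not a classifier model file")
        return cls(
            signature=[
                (e["locus_id"], Genotype(e["a1"], e["a2"])) for e in payload["signature"]
            ],
            cutoff=payload["cutoff"],
            mode=payload["mode"],
        )


@dataclass
class RocResult:
    thresholds: list[float]
    tpr: list[float]
    fpr: list[float]
    auc: float
    optimal_cutoff: float
    accuracy_at_cutoff: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        )

    def plot(self, ax=None):
        """ROC curve on a matplotlib axes (created if not given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], linestyle=":", color="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"AUC = {self.auc:.3f}")
        return ax


@dataclass
class ConfusionMatrix:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else float("nan")

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP) if self.TN + self.FP else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.TP + self.FP + self.FN + self.TN
        return (self.TP + self.TN) / total if total else float("nan")

    @property
    def odds_ratio(self) -> float:
        """(TP/FP)/(FN/TN), Haldane-corrected when any cell is zero."""
        return locus_odds_ratio((self.TP, self.FP, self.FN, self.TN))


def score_sample(
    calls: Mapping[str, Optional[Genotype]],
    model: ClassifierModel,
    min_called_frac: float = 0.5,
) -> Optional[float]:
    """Fraction of called signature loci carrying the risk genotype.

    Missing calls drop out of both numerator and denominator.  Returns
    None (unscorable) when no signature locus is called.  A second return
    channel is unnecessary for low-confidence flagging: compare the
    number of called loci against ``min_called_frac`` via
    :func:`n_signature_called` if needed.
    """
    n_called = 0
    n_risk = 0
    for locus_id, ref_genotype in model.signature:
        call = calls.get(locus_id)
        if call is None:
            continue
        n_called += 1
        if model.mode == "validation":
            n_risk += call == ref_genotype
        else:
            n_risk += call != ref_genotype
    if n_called == 0:
        return None
    return n_risk / n_called


def n_signature_called(calls: Mapping[str, Optional[Genotype]], model: ClassifierModel) -> int:
    return sum(1 for lid, _ in model.signature if calls.get(lid) is not None)


def _split_scores(scores: Sequence[float], labels: Sequence[str]):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    case = scores[labels == "case"]
    control = scores[labels == "control"]
    if len(case) == 0 or len(control) == 0:
        raise ValueError("both classes must be present")
    return case, control


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> RocResult:
    """ROC over the distinct observed scores; AUC by trapezoidal rule.

    The trapezoidal area over the ROC step function equals the
    Mann-Whitney concordance probability with ties credited 0.5.  The
    returned result also carries the accuracy-optimal cutoff.
    """
    case, control = _split_scores(scores, labels)
    thresholds = [float("inf")] + sorted({float(s) for s in scores}, reverse=True)
    tpr = [float(np.mean(case >= t)) if np.isfinite(t) else 0.0 for t in thresholds]
    fpr = [float(np.mean(control >= t)) if np.isfinite(t) else 0.0 for t in thresholds]
    auc = float(np.trapezoid(tpr, fpr))
    cutoff, accuracy = optimal_cutoff(scores, labels)
    return RocResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        optimal_cutoff=cutoff,
        accuracy_at_cutoff=accuracy,
    )


def optimal_cutoff(scores: Sequence[float], labels: Sequence[str]) -> tuple[float, float]:
    """Accuracy-maximizing cutoff under the ``score >= cutoff`` rule.

    Candidates are the distinct observed scores, plus a reject-all
    sentinel at 1.0 when no sample reaches it (so that classifying
    everyone healthy is expressible); accuracy ties are broken toward the
    larger cutoff (the more specific classifier).
    """
    case, control = _split_scores(scores, labels)
    candidates = {float(s) for s in scores}
    if max(candidates) < 1.0:
        candidates.add(1.0)
    best_cutoff, best_acc = None, -1.0
    for t in sorted(candidates):
        tp = int(np.sum(case >= t))
        tn = int(np.sum(control < t))
        acc = (tp + tn) / (len(case) + len(control))
        if acc >= best_acc:  # >= walks ties toward the larger cutoff
            best_cutoff, best_acc = t, acc
    return best_cutoff, best_acc


def evaluate(
    scores: Sequence[float], labels: Sequence[str], cutoff: float
) -> tuple[ConfusionMatrix, float, float, float]:
    """Confusion matrix, sensitivity, specificity and odds ratio at a cutoff."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    case, control = _split_scores(scores, labels)
    cm = ConfusionMatrix(
        TP=int(np.sum(case >= cutoff)),
        FN=int(np.sum(case < cutoff)),
        FP=int(np.sum(control >= cutoff)),
        TN=int(np.sum(control < cutoff)),
    )
    return cm, cm.sensitivity, cm.specificity, cm.odds_ratio


def _build_model(
    screened: Sequence[LocusStats], mode: str, cutoff: float = 0.5
) -> Optional[ClassifierModel]:
    signature = []
    for s in screened:
        if not s.informative:
            continue
        ref = s.predominant_cancer_genotype if mode == "validation" else s.modal_genotype
        signature.append((s.locus_id, ref))
    if not signature:
        return None
    return ClassifierModel(signature=signature, cutoff=cutoff, mode=mode)


@dataclass
class LoocvResult:
    """Held-out predictions and pooled/per-fold diagnostics."""

    predictions: pd.DataFrame  # sample_id, label, score, predicted, n_loci_used
    pooled_confusion: ConfusionMatrix
    pooled_sensitivity: float
    pooled_specificity: float
    fold_metrics: pd.DataFrame  # training-fold sensitivity/specificity/cutoff
    n_folds: int
    unpredictable: list[str]


def loocv(
    matrix: GenotypeMatrix,
    mode: str = "validation",
    q_cutoff: float = 0.0001,
    min_call_rate: float = 0.5,
    fixed_signature: bool = False,
) -> LoocvResult:
    """Leave-one-out cross-validation of the full screening + classifier fit.

    For each sample, the modal/predominant genotypes, the informative
    locus set, and the accuracy-optimal cutoff are refit on the remaining
    samples; the held-out sample is then scored and classified.  The fold
    count equals the total sample count.  ``fixed_signature=True``
    reproduces the optimistic variant in which the signature and the
    risk genotypes are fit once on the full cohort and only the cutoff is
    refit per fold.

    Pooled sensitivity/specificity are computed over the held-out
    predictions; per-fold training metrics are also returned because a
    single held-out sample has no sensitivity/specificity of its own.
    """
    for label in ("case", "control"):
        if len(matrix.samples_by_label(label)) < 2:
            raise ValueError(f"need at least 2 {label} samples for LOOCV")

    full_model = None
    if fixed_signature:
        screened_full = select_informative_loci(matrix, mode, q_cutoff, min_call_rate)
        full_model = _build_model(screened_full, mode)
        if full_model is None:
            raise ValueError("fixed-signature LOOCV: full-cohort signature is empty")

    rows, fold_rows, unpredictable = [], [], []
    tp = fp = fn = tn = 0
    for sample_id in matrix.sample_ids:
        train = matrix.drop_sample(sample_id)
        if fixed_signature:
            model = full_model
        else:
            screened = select_informative_loci(train, mode, q_cutoff, min_call_rate)
            model = _build_model(screened, mode)
        truth = matrix.labels[sample_id]
        if model is None:
            unpredictable.append(sample_id)
            rows.append(
                {
                    "sample_id": sample_id,
                    "label": truth,
                    "score": np.nan,
                    "predicted": "unpredictable",
                    "n_loci_used": 0,
                }
            )
            continue
        train_scores, train_labels = [], []
        for sid in train.sample_ids:
            sc = score_sample(train.sample_calls(sid), model)
            if sc is not None:
                train_scores.append(sc)
                train_labels.append(train.labels[sid])
        cutoff, _ = optimal_cutoff(train_scores, train_labels)
        _, fold_sens, fold_spec, _ = evaluate(train_scores, train_labels, cutoff)
        fold_rows.append(
            {
                "held_out": sample_id,
                "cutoff": cutoff,
                "train_sensitivity": fold_sens,
                "train_specificity": fold_spec,
                "n_signature": len(model.signature),
            }
        )

        calls = matrix.sample_calls(sample_id)
        score = score_sample(calls, model)
        if score is None:
            unpredictable.append(sample_id)
            predicted = "unpredictable"
        else:
            predicted = "at-risk" if score >= cutoff else "healthy"
            if truth == "case":
                tp += predicted == "at-risk"
                fn += predicted == "healthy"
            else:
                fp += predicted == "at-risk"
                tn += predicted == "healthy"
        rows.append(
            {
                "sample_id": sample_id,
                "label": truth,
                "score": score if score is not None else np.nan,
                "predicted": predicted,
                "n_loci_used": n_signature_called(calls, model),
            }
        )

    cm = ConfusionMatrix(TP=tp, FP=fp, FN=fn, TN=tn)
    return LoocvResult(
        predictions=pd.DataFrame(rows).set_index("sample_id"),
        pooled_confusion=cm,
        pooled_sensitivity=cm.sensitivity,
        pooled_specificity=cm.specificity,
        fold_metrics=pd.DataFrame(fold_rows).set_index("held_out"),
        n_folds=len(matrix.sample_ids),
        unpredictable=unpredictable,
    )


class MicrosatelliteRiskModel:
    """Case/control risk model over a genotype matrix.

    Fitting screens every locus for informativeness, assembles the
    signature with its per-locus risk genotypes, scores all samples,
    sweeps the ROC and selects the accuracy-optimal cutoff.

    Parameters
    ----------
    matrix
        Samples x loci genotype matrix with case/control labels.
    mode
        ``"validation"`` (predominance rule, the default) or
        ``"discovery"`` (Fisher exact + BH FDR).
    q_cutoff
        BH-adjusted significance cutoff for discovery mode.
    min_call_rate
        Loci called in fewer than this fraction of samples are excluded
        from screening.
    """

    def __init__(
        self,
        matrix: GenotypeMatrix,
        mode: str = "validation",
        q_cutoff: float = 0.0001,
        min_call_rate: float = 0.5,
    ):
        self.matrix = matrix
        self.mode = mode
        self.q_cutoff = q_cutoff
        self.min_call_rate = min_call_rate

    @classmethod
    def from_tsv(cls, matrix_path, labels_path, **kwargs) -> "MicrosatelliteRiskModel":
        return cls(GenotypeMatrix.from_tsv(matrix_path, labels_path), **kwargs)

    def fit(self) -> "RiskModelResults":
        screened = select_informative_loci(
            self.matrix, self.mode, self.q_cutoff, self.min_call_rate
        )
        classifier = _build_model(screened, self.mode)
        if classifier is None:
            raise ValueError("no informative loci: signature is empty")
        scores, labels, sample_ids = [], [], []
        for sid in self.matrix.sample_ids:
            sc = score_sample(self.matrix.sample_calls(sid), classifier)
            if sc is not None:
                scores.append(sc)
                labels.append(self.matrix.labels[sid])
                sample_ids.append(sid)
        roc = roc_auc(scores, labels)
        classifier.cutoff = roc.optimal_cutoff
        cm, sens, spec, odds = evaluate(scores, labels, roc.optimal_cutoff)
        return RiskModelResults(
            model=self,
            classifier=classifier,
            screened=list(screened),
            scores=pd.Series(scores, index=sample_ids, name="score"),
            score_labels=pd.Series(labels, index=sample_ids, name="label"),
            roc=roc,
            confusion=cm,
            sensitivity=sens,
            specificity=spec,
            odds_ratio=odds,
        )

    def loocv(self, fixed_signature: bool = False) -> LoocvResult:
        return loocv(
            self.matrix, self.mode, self.q_cutoff, self.min_call_rate, fixed_signature
        )


@dataclass
class RiskModelResults:
    """Fitted signature, cutoff and performance diagnostics."""

    model: MicrosatelliteRiskModel
    classifier: ClassifierModel
    screened: list[LocusStats]
    scores: pd.Series
    score_labels: pd.Series
    roc: RocResult
    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    odds_ratio: float

    @property
    def signature(self) -> list[tuple[str, Genotype]]:
        return self.classifier.signature

    @property
    def cutoff(self) -> float:
        return self.classifier.cutoff

    @property
    def auc(self) -> float:
        return self.roc.auc

    @property
    def min_risk_loci(self) -> int:
        """Smallest at-risk locus count at the cutoff on a fully called sample."""
        import math

        n = len(self.signature)
        return math.ceil(self.cutoff * n - 1e-12)

    def locus_table(self) -> pd.DataFrame:
        from .screen import stats_to_dataframe

        return stats_to_dataframe(self.screened)

    def predict(self, calls_or_matrix) -> pd.DataFrame:
        """Score and classify new samples with the fitted model."""
        if isinstance(calls_or_matrix, GenotypeMatrix):
            items = [
                (sid, calls_or_matrix.sample_calls(sid))
                for sid in calls_or_matrix.sample_ids
            ]
        else:
            items = list(calls_or_matrix.items())
        rows = []
        for sid, calls in items:
            score = score_sample(calls, self.classifier)
            rows.append(
                {
                    "sample_id": sid,
                    "score": score if score is not None else np.nan,
                    "call": (
                        "unscorable"
                        if score is None
                        else "at-risk" if score >= self.classifier.cutoff else "healthy"
                    ),
                    "n_loci_used": n_signature_called(calls, self.classifier),
                }
            )
        return pd.DataFrame(rows).set_index("sample_id")

    def loocv(self, fixed_signature: bool = False) -> LoocvResult:
        return self.model.loocv(fixed_signature=fixed_signature)

    def plot_roc(self, ax=None):
        return self.roc.plot(ax=ax)

    def summary(self) -> str:
        n_cases = int((self.score_labels == "case").sum())
        n_controls = int((self.score_labels == "control").sum())
        lines = [
            "Microsatellite risk classifier",
            "=" * 46,
            f"mode:                {self.model.mode}",
            f"samples scored:      {len(self.scores)} ({n_cases} case / {n_controls} control)",
            f"loci screened:       {len(self.screened)}",
            f"signature loci:      {len(self.signature)}",
            f"score cutoff:        {self.cutoff:.4f}"
            f"  (>= {self.min_risk_loci} of {len(self.signature)} risk genotypes)",
            f"AUC:                 {self.auc:.4f}",
            f"sensitivity:         {self.sensitivity:.4f}",
            f"specificity:         {self.specificity:.4f}",
            f"odds ratio:          {self.odds_ratio:.2f}",
            "-" * 46,
            "signature (locus, risk genotype):",
        ]
        for lid, g in self.signature:
            lines.append(f"  {lid:<28} {g.a1}/{g.a2}")
        return "\n".join(lines)
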