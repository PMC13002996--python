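"""Enhancer functional-state classification from per-CpG modification states.

Each enhancer is represented as the ordered sequence of its CpG sites'
normalised 4-state vectors (x_ambiguous_modC, x_mC, x_hmC, x_C): raw call
counts are normalised by the total at each CpG per replicate, then averaged
across replicates.  Labels are 0 = active, 1 = poised, 2 = primed.
Chromosome-level holdout (chromosome 1 by default) separates training from
evaluation.  Evaluation reports one-vs-rest precision-recall and ROC curves
with trapezoidal AUC per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import precision_recall_curve, roc_curve

from .attention import AttentionClassifier, ModelConfig
from .errors import InvalidInputError
from .quant import MethylTable
from .reference import EnhancerSet

logger = logging.getLogger(__name__)

LABEL_OF_CLASS = {"active": 0, "poised": 1, "primed": 2}
CLASS_OF_LABEL = {v: k for k, v in LABEL_OF_CLASS.items()}


@dataclass
class EnhancerSample:
    """One enhancer: ordered per-CpG normalised state vectors plus a label."""

    sample_id: str
    chrom: str
    vectors: np.ndarray          # (k, 4) rows (x_X, x_M, x_H, x_U)
    label: int                   # 0 active, 1 poised, 2 primed

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 4:
            raise InvalidInputError("vectors must have shape (k, 4)")
        if self.label not in (0, 1, 2):
            raise InvalidInputError("label must be 0, 1 or 2")


def prepare_samples(
    tables: Sequence[MethylTable],
    enhancers: EnhancerSet,
    min_cov: int = 1,
) -> list[EnhancerSample]:
    """Build one sample per enhancer from replicate call-count tables.

    Per replicate, each CpG's (X, M, H, U) counts are normalised by their
    total; vectors are then averaged across the replicates that cover the
    site.  CpGs are ordered by coordinate.  Enhancers with zero covered CpGs
    are dropped with a warning.
    """
    if not tables:
        raise InvalidInputError("need at least one replicate table")
    frac_by_rep = []
    for t in tables:
        df = t.df
        tot = df[["n_X", "n_M", "n_H", "n_U"]].sum(axis=1)
        keep = tot >= max(min_cov, 1)
        fr = df.loc[keep, ["n_X", "n_M", "n_H", "n_U"]].div(tot[keep], axis=0)
        frac_by_rep.append(fr)

    samples: list[EnhancerSample] = []
    for i, (chrom, start, end, cls) in enumerate(enhancers.intervals):
        per_site: dict[tuple[int, str], list[np.ndarray]] = {}
        for fr in frac_by_rep:
            if fr.empty:
                continue
            idx = fr.index
            sel = (
                (idx.get_level_values("chrom") == chrom)
                & (idx.get_level_values("pos") >= start)
                & (idx.get_level_values("pos") < end)
            )
            for (c, pos, strand), row in fr[sel].iterrows():
                per_site.setdefault((int(pos), strand), []).append(
                    row.to_numpy())
        if not per_site:
            logger.warning("enhancer %s:%d-%d (%s) has no covered CpGs; "
                           "dropped", chrom, start, end, cls)
            continue
        keys = sorted(per_site)
        vectors = np.vstack([np.mean(per_site[k], axis=0) for k in keys])
        samples.append(EnhancerSample(
            sample_id=f"enh{i}", chrom=chrom, vectors=vectors,
            label=LABEL_OF_CLASS[cls],
        ))
    return samples


def split_by_chromosome(
    samples: Sequence[EnhancerSample], holdout: str = "chr1"
) -> tuple[list[EnhancerSample], list[EnhancerSample]]:
    """Exact partition: samples on the holdout chromosome form the test set."""
    test = [s for s in samples if s.chrom == holdout]
    train = [s for s in samples if s.chrom != holdout]
    if not test:
        raise InvalidInputError(f"holdout chromosome {holdout!r} has no samples")
    return train, test


def train(samples: Sequence[EnhancerSample],
          config: ModelConfig | None = None) -> AttentionClassifier:
    """Fit the self-attention classifier on training samples."""
    model = AttentionClassifier(config)
    model.fit([s.vectors for s in samples], [s.label for s in samples])
    return model


@dataclass
class EvalReport:
    """One-vs-rest PR/ROC curves, AUCs and confusion counts per class."""

    roc: dict[str, dict | None] = field(default_factory=dict)
    pr: dict[str, dict | None] = field(default_factory=dict)
    confusion: np.ndarray = field(default_factory=lambda: np.zeros((3, 3), int))
    accuracy: float = float("nan")

    @property
    def macro_roc_auc(self) -> float:
        aucs = [v["auc"] for v in self.roc.values() if v is not None]
        return float(np.mean(aucs)) if aucs else float("nan")

    @property
    def macro_pr_auc(self) -> float:
        aucs = [v["auc"] for v in self.pr.values() if v is not None]
        return float(np.mean(aucs)) if aucs else float("nan")


def evaluate(model: AttentionClassifier,
             samples: Sequence[EnhancerSample]) -> EvalReport:
    """Score a test set: per-class one-vs-rest curves from softmax scores.

    Classes absent from the test set get undefined (None) curves, reported
    as such.
    """
    if not samples:
        raise InvalidInputError("test set must be non-empty")
    probs = model.predict_proba([s.vectors for s in samples])
    y = np.array([s.label for s in samples])
    pred = probs.argmax(axis=1)
    n_cls = probs.shape[1]
    report = EvalReport()
    report.confusion = np.zeros((n_cls, n_cls), dtype=int)
    for t, p in zip(y, pred):
        report.confusion[t, p] += 1
    report.accuracy = float(np.mean(pred == y))
    for cls in range(n_cls):
        name = CLASS_OF_LABEL.get(cls, str(cls))
        binary = (y == cls).astype(int)
        if binary.sum() == 0 or binary.sum() == len(y):
            report.roc[name] = None
            report.pr[name] = None
            continue
        fpr, tpr, _ = roc_curve(binary, probs[:, cls])
        prec, rec, _ = precision_recall_curve(binary, probs[:, cls])
        report.roc[name] = {"fpr": fpr, "tpr": tpr,
                            "auc": float(_auc(fpr, tpr))}
        report.pr[name] = {"precision": prec, "recall": rec,
                           "auc": float(_auc(rec, prec))}
    return report


def cross_evaluate(model: AttentionClassifier,
                   samples: Sequence[EnhancerSample]) -> EvalReport:
    """Apply a model trained on one data source to samples from another."""
    return evaluate(model, samples)


# ---------------------------------------------------------------------------
# direct synthetic sample generator (deep-pipeline emulation)


#: miscall probability of each called state given the true state, emulating
#: near-ideal chemistry through the resolver (rows: true U / M / H)
_CALL_GIVEN_TRUE = {
    "U": np.array([0.004, 0.004, 0.002, 0.990]),   # (X, M, H, U)
    "M": np.array([0.006, 0.984, 0.006, 0.004]),
    "H": np.array([0.006, 0.006, 0.984, 0.004]),
}


def simulate_enhancer_samples(
    signatures: dict[str, tuple[float, float]],
    n_per_class: int = 150,
    cpgs_range: tuple[int, int] = (20, 60),
    coverage: int = 50,
    contamination: float = 0.0,
    background: tuple[float, float] = (0.70, 0.03),
    chromosomes: Sequence[str] = ("chr1", "chr2", "chr3", "chr4"),
    seed: int = 0,
) -> list[EnhancerSample]:
    """Draw enhancer samples directly at the normalised-vector level.

    Per CpG a binary truth state is drawn from the class signature
    (p_5mC, p_5hmC) — or from the ``background`` signature with probability
    ``contamination``, emulating the signal dilution of an unenriched
    whole-genome library — and observed counts follow a multinomial with a
    small miscall rate at the given coverage.  Chromosomes are assigned
    round-robin so chromosome-holdout splits are balanced.
    """
    rng = np.random.default_rng(seed)
    samples: list[EnhancerSample] = []
    i = 0
    for cls, (pm, ph) in signatures.items():
        for _ in range(n_per_class):
            k = int(rng.integers(cpgs_range[0], cpgs_range[1] + 1))
            vecs = np.empty((k, 4))
            for j in range(k):
                use_pm, use_ph = (background if rng.random() < contamination
                                  else (pm, ph))
                u = rng.random()
                true = "M" if u < use_pm else ("H" if u < use_pm + use_ph
                                               else "U")
                counts = rng.multinomial(coverage, _CALL_GIVEN_TRUE[true])
                vecs[j] = counts / counts.sum()
            samples.append(EnhancerSample(
                sample_id=f"sim{i}",
                chrom=chromosomes[i % len(chromosomes)],
                vectors=vecs,
                label=LABEL_OF_CLASS[cls],
            ))
            i += 1
    return samples
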