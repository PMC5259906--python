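"""Model/Results facade for binding-residue prediction.

:class:`BindingSiteModel` is built from data (protein records, PSSM
profiles, site annotations) plus a :class:`PipelineConfig`; ``fit()``
returns a :class:`BindingSiteResults` carrying the fitted RBF network,
the SAAP selection made on the training data, and a ``summary()``
table.  :func:`cross_validate` runs protein-level k-fold CV, refitting
the SAAP selection inside every training fold so no selection
information leaks into the held-out proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import encoding, evaluation, rbfn, saap
from .io_formats import (
    ConsistencyError,
    ParameterError,
    PredictionRecord,
    ProteinRecord,
    PSSMProfile,
    SiteAnnotationTable,
    attach_annotations,
)

ENCODINGS = ("pssm", "binary", "blosum62", "pam250", "pssm+saap")


@dataclass
class PipelineConfig:
    """End-to-end settings; the defaults are the method's published
    operating point (window 19, bandwidth 5, p < 0.030212, 160 pairs)."""

    window: int = 19
    sigma: float = rbfn.DEFAULT_SIGMA
    ridge: float = rbfn.DEFAULT_RIDGE
    alpha: float = saap.DEFAULT_ALPHA
    max_saaps: int = saap.DEFAULT_MAX_K
    encoding: str = "pssm+saap"
    threshold: float = 0.0
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 1:
            raise ParameterError(f"window must be odd, got {self.window}")
        if self.encoding not in ENCODINGS:
            raise ParameterError(
                f"encoding {self.encoding!r} not one of {ENCODINGS}"
            )
        if self.folds < 2:
            raise ParameterError("folds must be >= 2")

    @property
    def uses_pssm(self) -> bool:
        return self.encoding in ("pssm", "pssm+saap")

    @property
    def uses_saap(self) -> bool:
        return self.encoding == "pssm+saap"


def _base_features(
    fragments: Sequence[encoding.WindowFragment],
    config: PipelineConfig,
    profiles_by_id: Dict[str, PSSMProfile],
    records_by_id: Dict[str, ProteinRecord],
) -> np.ndarray:
    if config.uses_pssm:
        rows = []
        for frag in fragments:
            profile = profiles_by_id.get(frag.protein_id)
            if profile is None:
                raise ConsistencyError(
                    f"no PSSM profile for protein {frag.protein_id!r}"
                )
            rows.append(encoding.encode_pssm_window(profile, frag))
    else:
        table = encoding.substitution_encoding(config.encoding.upper())
        rows = [
            encoding.encode_substitution_window(
                records_by_id[frag.protein_id], frag, table
            )
            for frag in fragments
        ]
    return np.asarray(rows, dtype=float)


def _augment_matrix(
    base: np.ndarray,
    fragments: Sequence[encoding.WindowFragment],
    selection: saap.SAAPSelection,
) -> np.ndarray:
    if not selection.pairs:
        return base
    extra = np.zeros((base.shape[0], len(selection.pairs)))
    index = {p: j for j, p in enumerate(selection.pairs)}
    for i, frag in enumerate(fragments):
        for pair in saap.enumerate_pairs(frag):
            j = index.get(pair)
            if j is not None:
                extra[i, j] = 1.0
    return np.hstack([base, extra])


class BindingSiteModel:
    """Binding-residue prediction model built from sequence data.

    Parameters
    ----------
    records : sequence of ProteinRecord
        Training proteins; binding annotations may already be attached
        or supplied separately via ``annotations``.
    profiles : sequence of PSSMProfile, optional
        Required for PSSM-based encodings.
    annotations : SiteAnnotationTable, optional
        1-based binding positions per protein id.
    config : PipelineConfig, optional
    """

    def __init__(
        self,
        records: Sequence[ProteinRecord],
        profiles: Optional[Sequence[PSSMProfile]] = None,
        annotations: Optional[SiteAnnotationTable] = None,
        config: Optional[PipelineConfig] = None,
    ):
        self.config = config or PipelineConfig()
        if annotations is not None:
            records = attach_annotations(records, annotations)
        self.records = list(records)
        self.profiles = list(profiles or [])
        self._records_by_id = {r.id: r for r in self.records}
        self._profiles_by_id = {p.protein_id: p for p in self.profiles}
        if self.config.uses_pssm:
            missing = [
                r.id for r in self.records if r.id not in self._profiles_by_id
            ]
            if missing:
                raise ConsistencyError(
                    f"PSSM encoding requested but profile missing for: {missing}"
                )
            for rec in self.records:
                if len(self._profiles_by_id[rec.id]) != len(rec.sequence):
                    raise ConsistencyError(
                        f"profile/sequence length mismatch for {rec.id}"
                    )

    @classmethod
    def from_files(
        cls,
        fasta_path,
        pssm_dir=None,
        annotations_path=None,
        config: Optional[PipelineConfig] = None,
    ) -> "BindingSiteModel":
        """Build a model from a FASTA file, a directory of ``<id>.pssm``
        ASCII profiles and an annotation TSV."""
        from pathlib import Path

        from . import io_formats

        records = io_formats.read_fasta(fasta_path)
        annotations = (
            io_formats.read_site_annotations(annotations_path)
            if annotations_path
            else None
        )
        config = config or PipelineConfig()
        profiles = []
        if config.uses_pssm:
            if pssm_dir is None:
                raise ParameterError(
                    f"encoding {config.encoding!r} requires a PSSM directory"
                )
            for rec in records:
                path = Path(pssm_dir) / f"{rec.id}.pssm"
                if not path.exists():
                    raise ConsistencyError(
                        f"missing PSSM file for protein {rec.id!r}: {path}"
                    )
                profiles.append(
                    io_formats.read_pssm_ascii(
                        path, len(rec.sequence), sequence=rec.sequence
                    )
                )
        return cls(records, profiles, annotations, config)

    def fragments(self) -> List[encoding.WindowFragment]:
        out: List[encoding.WindowFragment] = []
        for rec in self.records:
            out.extend(encoding.extract_windows(rec, self.config.window))
        return out

    def fit(self) -> "BindingSiteResults":
        """Fit the SAAP selection (when configured) and the RBF network
        on all proteins of this model."""
        fragments = self.fragments()
        selection = saap.SAAPSelection(pairs=[])
        pair_stats: List[saap.PairStatistic] = []
        if self.config.uses_saap:
            selection, pair_stats = saap.fit_selection(
                fragments, alpha=self.config.alpha, max_k=self.config.max_saaps
            )
        base = _base_features(
            fragments, self.config, self._profiles_by_id, self._records_by_id
        )
        features = _augment_matrix(base, fragments, selection)
        labels = np.array([f.label for f in fragments])
        network = rbfn.fit(
            rbfn.TrainingSet(features, labels),
            sigma=self.config.sigma,
            ridge=self.config.ridge,
            threshold=self.config.threshold,
        )
        return BindingSiteResults(
            model=self,
            network=network,
            selection=selection,
            pair_stats=pair_stats,
            n_train=len(fragments),
            n_positive=int(labels.sum()),
        )


@dataclass
class BindingSiteResults:
    """A fitted predictor: RBF network + SAAP selection + settings."""

    model: BindingSiteModel
    network: rbfn.RBFModel
    selection: saap.SAAPSelection
    pair_stats: List[saap.PairStatistic]
    n_train: int
    n_positive: int

    @property
    def config(self) -> PipelineConfig:
        return self.model.config

    def _encode(
        self,
        records: Sequence[ProteinRecord],
        profiles: Optional[Sequence[PSSMProfile]],
    ) -> Tuple[List[encoding.WindowFragment], np.ndarray]:
        config = self.config
        records_by_id = {r.id: r for r in records}
        profiles_by_id = {p.protein_id: p for p in profiles or []}
        fragments: List[encoding.WindowFragment] = []
        for rec in records:
            fragments.extend(encoding.extract_windows(rec, config.window))
        base = _base_features(fragments, config, profiles_by_id, records_by_id)
        features = _augment_matrix(base, fragments, self.selection)
        if features.shape[1] != self.network.n_features:
            raise ConsistencyError(
                f"feature length {features.shape[1]} does not match the "
                f"fitted model's {self.network.n_features}"
            )
        return fragments, features

    def predict(
        self,
        records: Sequence[ProteinRecord],
        profiles: Optional[Sequence[PSSMProfile]] = None,
    ) -> List[PredictionRecord]:
        """Score every residue of ``records``; label 1 where the score
        exceeds the decision threshold."""
        fragments, features = self._encode(records, profiles)
        scores = rbfn.score(self.network, features)
        labels = (scores > self.network.threshold).astype(int)
        return [
            PredictionRecord(
                protein_id=f.protein_id,
                position=f.center + 1,
                score=float(s),
                label=int(l),
            )
            for f, s, l in zip(fragments, scores, labels)
        ]

    def save(self, path) -> None:
        rbfn.save_model(
            self.network,
            path,
            selection=self.selection,
            meta={
                "window": self.config.window,
                "encoding": self.config.encoding,
                "n_train": self.n_train,
                "n_positive": self.n_positive,
            },
        )

    @staticmethod
    def load(path) -> Tuple[rbfn.RBFModel, saap.SAAPSelection, dict]:
        return rbfn.load_model(path)

    def summary(self) -> str:
        c = self.config
        lines = [
            "Binding-site RBF network",
            "========================",
            f"training residues    {self.n_train} ({self.n_positive} binding)",
            f"encoding             {c.encoding} (window {c.window})",
            f"feature length       {self.network.n_features}",
            f"selected pairs       {len(self.selection)} "
            f"(alpha {self.selection.alpha}, cap {self.selection.max_k})",
            f"kernel bandwidth     {self.network.sigma}",
            f"ridge                {self.network.ridge}",
            f"decision threshold   {self.network.threshold}",
        ]
        if self.selection.pairs:
            lines.append(
                "top pairs            " + " ".join(self.selection.pairs[:10])
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResults:
    """Pooled protein-level cross-validation results."""

    config: PipelineConfig
    k: int
    seed: int
    assignment: Dict[str, int]
    fold_reports: List[evaluation.MetricsReport]
    pooled: evaluation.MetricsReport
    roc_points: np.ndarray
    selections: List[saap.SAAPSelection] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "settings": asdict(self.config),
            "k": self.k,
            "seed": self.seed,
            "folds": {pid: fold for pid, fold in sorted(self.assignment.items())},
            "per_fold": [r.to_dict() for r in self.fold_reports],
            "pooled": self.pooled.to_dict(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def summary(self) -> str:
        p = self.pooled
        rows = [
            f"Protein-level {self.k}-fold cross-validation "
            f"(seed {self.seed}, encoding {self.config.encoding})",
            f"pooled counts  TP={p.counts.TP} FP={p.counts.FP} "
            f"TN={p.counts.TN} FN={p.counts.FN}",
        ]
        r = p.rounded()
        rows.append(
            f"sensitivity {r['sensitivity']}%  specificity {r['specificity']}%  "
            f"accuracy {r['accuracy']}%  MCC {r['mcc']}  AUC {r['auc']}"
        )
        return "\n".join(rows)


def cross_validate(
    records: Sequence[ProteinRecord],
    profiles: Optional[Sequence[PSSMProfile]] = None,
    annotations: Optional[SiteAnnotationTable] = None,
    config: Optional[PipelineConfig] = None,
    k: Optional[int] = None,
    seed: Optional[int] = None,
) -> CVResults:
    """Protein-level k-fold CV with per-fold SAAP refitting.

    All residues of one protein share a fold.  Scores and labels are
    pooled across the held-out folds before computing the confusion
    counts, metrics and ROC/AUC.
    """
    config = config or PipelineConfig()
    k = k if k is not None else config.folds
    seed = seed if seed is not None else config.seed
    if annotations is not None:
        records = attach_annotations(records, annotations)
    records = list(records)
    assignment = evaluation.protein_kfold(records, k=k, seed=seed)
    profiles = list(profiles or [])
    records_by_id = {r.id: r for r in records}
    profiles_by_id = {p.protein_id: p for p in profiles}

    fragments: List[encoding.WindowFragment] = []
    for rec in records:
        fragments.extend(encoding.extract_windows(rec, config.window))
    base = _base_features(fragments, config, profiles_by_id, records_by_id)
    labels = np.array([f.label for f in fragments])
    frag_fold = np.array([assignment[f.protein_id] for f in fragments])

    all_scores = np.empty(len(fragments))
    all_pred = np.empty(len(fragments), dtype=int)
    fold_reports: List[evaluation.MetricsReport] = []
    selections: List[saap.SAAPSelection] = []
    for fold in range(k):
        test_mask = frag_fold == fold
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        train_frags = [fragments[i] for i in train_idx]
        selection = saap.SAAPSelection(pairs=[])
        if config.uses_saap:
            selection, _ = saap.fit_selection(
                train_frags, alpha=config.alpha, max_k=config.max_saaps
            )
        selections.append(selection)
        train_X = _augment_matrix(base[train_idx], train_frags, selection)
        test_X = _augment_matrix(
            base[test_idx], [fragments[i] for i in test_idx], selection
        )
        network = rbfn.fit(
            rbfn.TrainingSet(train_X, labels[train_idx]),
            sigma=config.sigma,
            ridge=config.ridge,
            threshold=config.threshold,
        )
        fold_scores = rbfn.score(network, test_X)
        fold_pred = (fold_scores > config.threshold).astype(int)
        all_scores[test_idx] = fold_scores
        all_pred[test_idx] = fold_pred
        fold_truth = labels[test_idx]
        counts = evaluation.confusion(fold_truth, fold_pred)
        fold_reports.append(
            evaluation.metrics(counts, scores=fold_scores, truth=fold_truth)
        )
    pooled_counts = evaluation.confusion(labels, all_pred)
    pooled = evaluation.metrics(pooled_counts, scores=all_scores, truth=labels)
    points = evaluation.roc_curve(all_scores, labels)
    return CVResults(
        config=config,
        k=k,
        seed=seed,
        assignment=assignment,
        fold_reports=fold_reports,
        pooled=pooled,
        roc_points=points,
        selections=selections,
    )
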