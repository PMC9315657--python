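"""End-to-end hybrid BoVW model: dataset in, fitted results out.

:class:`HybridBovwModel` is built from a labeled dataset plus a
:class:`~mribovw.config.PipelineConfig`; ``fit()`` runs the full
pipeline — stratified split, dense Gaussian and nonlinear descriptor
extraction, variance-based selection, per-family k-means vocabularies,
histogram encoding, hybridization, classifier training — and returns a
:class:`HybridBovwResults` carrying the vocabularies, the trained
model, the held-out evaluation and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classification import (
    EvaluationReport,
    TrainedModel,
    classifier_registry,
    evaluate,
    predict,
    train_svm,
)
from .config import PipelineConfig
from .dataset_io import (
    GrayImage,
    LabeledDataset,
    SplitIndex,
    load_dataset,
    stratified_split,
)
from .descriptors import DescriptorSet
from .gaussian_features import dense_extract_gaussian
from .nonlinear_features import dense_extract_nonlinear
from .vocabulary_encoding import (
    Vocabulary,
    encode_histogram,
    fit_vocabulary,
    hybridize,
    select_strongest,
)

logger = logging.getLogger(__name__)


def extract_both_families(
    img: GrayImage, config: PipelineConfig, image_id: int = 0
) -> tuple[DescriptorSet, DescriptorSet]:
    """Dense Gaussian and nonlinear descriptors for one image."""
    g = dense_extract_gaussian(
        img,
        grid_step=config.grid_step,
        scales=config.gaussian_scales,
        image_id=image_id,
    )
    n = dense_extract_nonlinear(
        img,
        grid_step=config.grid_step,
        scales=config.nonlinear_scales,
        image_id=image_id,
        contrast_percentile=config.contrast_percentile,
        aos_substeps=config.aos_substeps,
        conductivity_kind=config.conductivity,
    )
    return g, n


@dataclass
class HybridBovwResults:
    """Fitted pipeline artifacts and held-out evaluation."""

    config: PipelineConfig
    split: SplitIndex
    vocab_gaussian: Vocabulary
    vocab_nonlinear: Vocabulary
    model: TrainedModel
    report: EvaluationReport
    n_descriptors_pooled: dict
    n_descriptors_kept: dict
    family_reports: dict = field(default_factory=dict)
    train_features: np.ndarray | None = None
    test_features: np.ndarray | None = None
    train_labels: list | None = None
    test_labels: list | None = None

    @property
    def hybrid_length(self) -> int:
        return self.vocab_gaussian.k + self.vocab_nonlinear.k

    def encode_image(self, img: GrayImage) -> np.ndarray:
        """Hybrid feature vector of a new image under the frozen vocabularies."""
        g, n = extract_both_families(img, self.config)
        gb = encode_histogram(g, self.vocab_gaussian, self.config.histogram_norm)
        nb = encode_histogram(n, self.vocab_nonlinear, self.config.histogram_norm)
        return hybridize(gb, nb, normalization=self.config.histogram_norm).values

    def predict_images(self, images: list[GrayImage]) -> np.ndarray:
        feats = np.vstack([self.encode_image(im) for im in images])
        return predict(self.model, feats)

    def summary(self) -> str:
        lines = [
            "Hybrid BoVW classification results",
            "=" * 40,
            f"descriptor length          : 64 per local feature",
            f"vocabulary size (per family): {self.vocab_gaussian.k} + {self.vocab_nonlinear.k}",
            f"hybrid vector length       : {self.hybrid_length}",
            f"train / test images        : {len(self.split.train_indices)} / {len(self.split.test_indices)}",
        ]
        for fam in ("gaussian", "nonlinear"):
            pooled = self.n_descriptors_pooled[fam]
            kept = self.n_descriptors_kept[fam]
            lines.append(
                f"{fam:9s} pool: {pooled} descriptors, kept {kept} "
                f"({100.0 * kept / pooled:.1f}%)"
            )
        lines.append(f"held-out accuracy          : {self.report.accuracy:.4f}")
        for c, tpr in zip(self.report.classes, self.report.per_class_tpr):
            lines.append(f"  TPR[{c}]: {tpr:.4f}")
        for fam, rep in self.family_reports.items():
            lines.append(f"{fam}-only accuracy: {rep.accuracy:.4f}")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_file(out / "config.yaml")
        from .dataset_io import save_split

        save_split(self.split, out / "split.tsv")
        self.vocab_gaussian.save(out / "vocab_gaussian.npz")
        self.vocab_nonlinear.save(out / "vocab_nonlinear.npz")
        self.model.save(out / "model.joblib")
        self.report.save(out / "evaluation.tsv")


@dataclass
class HybridBovwModel:
    """The hybrid Gaussian + nonlinear BoVW classification model.

    Parameters
    ----------
    dataset : LabeledDataset
        Class-per-folder image collection.
    config : PipelineConfig, optional
        Pipeline tunables; defaults reproduce the standard setup
        (8-pixel grid, scales 17/34/51/68 and 16/32/48/64, 80% keep
        fraction, k = 400 words per family, 80/20 stratified split,
        linear SVM).
    """

    dataset: LabeledDataset
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @classmethod
    def from_folder(
        cls, root: str | Path, config: PipelineConfig | None = None
    ) -> "HybridBovwModel":
        return cls(dataset=load_dataset(root), config=config or PipelineConfig())

    def _extract_all(self) -> tuple[list[DescriptorSet], list[DescriptorSet]]:
        g_sets, n_sets = [], []
        for i in range(len(self.dataset)):
            img = self.dataset.load_image(i)
            g, n = extract_both_families(img, self.config, image_id=i)
            g_sets.append(g)
            n_sets.append(n)
        return g_sets, n_sets

    def fit(
        self,
        evaluate_single_families: bool = False,
        keep_features: bool = False,
    ) -> HybridBovwResults:
        """Run the full pipeline and return the fitted results."""
        cfg = self.config
        split = stratified_split(self.dataset, cfg.split_fraction, cfg.split_seed)
        g_sets, n_sets = self._extract_all()

        vocabularies = {}
        pooled_counts, kept_counts = {}, {}
        for fam, sets in (("gaussian", g_sets), ("nonlinear", n_sets)):
            pool = DescriptorSet.concatenate(
                [sets[i] for i in split.train_indices]
            )
            pooled_counts[fam] = len(pool)
            kept = select_strongest(pool, cfg.keep_fraction)
            kept_counts[fam] = len(kept)
            logger.info(
                "%s: pooled %d descriptors, kept %d (%.1f%%)",
                fam, len(pool), len(kept), 100.0 * len(kept) / len(pool),
            )
            vocabularies[fam] = fit_vocabulary(kept, k=cfg.vocab_k, seed=cfg.kmeans_seed)

        def hybrid_features(indices):
            rows = []
            for i in indices:
                gb = encode_histogram(g_sets[i], vocabularies["gaussian"], cfg.histogram_norm)
                nb = encode_histogram(n_sets[i], vocabularies["nonlinear"], cfg.histogram_norm)
                rows.append(hybridize(gb, nb, image_id=i).values)
            return np.vstack(rows)

        labels = self.dataset.labels
        X_train = hybrid_features(split.train_indices)
        X_test = hybrid_features(split.test_indices)
        y_train = [labels[i] for i in split.train_indices]
        y_test = [labels[i] for i in split.test_indices]

        model, report = self._train_and_eval(X_train, y_train, X_test, y_test)

        family_reports = {}
        if evaluate_single_families:
            k = cfg.vocab_k
            for fam, sl in (("gaussian", slice(0, k)), ("nonlinear", slice(k, 2 * k))):
                fam_model, fam_report = self._train_and_eval(
                    X_train[:, sl], y_train, X_test[:, sl], y_test
                )
                family_reports[fam] = fam_report

        return HybridBovwResults(
            config=cfg,
            split=split,
            vocab_gaussian=vocabularies["gaussian"],
            vocab_nonlinear=vocabularies["nonlinear"],
            model=model,
            report=report,
            n_descriptors_pooled=pooled_counts,
            n_descriptors_kept=kept_counts,
            family_reports=family_reports,
            train_features=X_train if keep_features else None,
            test_features=X_test if keep_features else None,
            train_labels=y_train if keep_features else None,
            test_labels=y_test if keep_features else None,
        )

    def _train_and_eval(self, X_train, y_train, X_test, y_test):
        cfg = self.config
        if cfg.classifier == "svm":
            model = train_svm(
                X_train, y_train, kernel=cfg.svm_kernel, C=cfg.svm_c,
                seed=cfg.kmeans_seed,
            )
            report = evaluate(model, X_test, y_test)
        else:
            clf = classifier_registry(cfg.classifier, seed=cfg.kmeans_seed)
            clf.fit(X_train, y_train)
            model = clf
            report = evaluate(clf, X_test, y_test)
        return model, report
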