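"""End-to-end orchestration of one biomarker-discovery run.

For a given two-class comparison the pipeline chains: subset ->
univariate t-test/fold-change screen -> autoscale -> PCA -> batch SOM
(+ PCA of neuron weights) -> PLS-DA backward elimination with repeated
leave-more-out CV -> metrics, and collects everything in a
:class:`ComparisonReport`.  A master seed fans out to per-stage seeds
through ``numpy.random.SeedSequence`` spawn keys, so each stage is
independently re-runnable and the whole run is reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (
    AbundanceDataset,
    ComparisonDesign,
    DEFAULT_DESIGNS,
    autoscale,
    subset_for_design,
)
from .decomposition import PCAModel, pca_fit, pca_on_som_weights
from .plsda import coefficient_report
from .selection import CVScheme, SelectionTrace, backward_eliminate
from .som import SOMConfig, SOMModel, som_fit, top_map
from .univariate import UnivariateResult, ttest_fc_screen

__all__ = ["PipelineConfig", "ComparisonReport", "run_comparison", "run_all", "overlap_summary"]

_STAGES = ("univariate", "som", "selection")


def _stage_seed(master_seed: int, design_name: str, stage: str) -> int:
    """Deterministic per-stage seed: spawn key = (design hash, stage index)."""
    key = (zlib.crc32(design_name.encode()) % (2**16), _STAGES.index(stage))
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Knobs of a full comparison run.

    ``n_repeats`` is the CV repeat count (1000 by default, matching the
    leave-more-out protocol; reduce for quick runs), ``max_lv`` caps the
    latent variables considered, and the SOM preset is chosen per
    design: 10x10 / 300 epochs when a class pools several timepoints,
    8x8 / 200 epochs for pairwise contrasts.
    """

    seed: int = 0
    n_repeats: int = 1000
    max_lv: int = 7
    p_threshold: float = 0.05
    fc_upper: float = 1.3
    fc_lower: float = 0.769
    pca_components: int = 5
    replicate_aware_cv: bool = False


@dataclass
class ComparisonReport:
    design: ComparisonDesign
    n_samples: int
    univariate: UnivariateResult
    pca: PCAModel
    som: SOMModel
    som_top_map: pd.DataFrame
    som_weights_pca: PCAModel
    som_neuron_classes: pd.Series
    trace: SelectionTrace
    protein_ids: list[str]
    seeds: dict

    @property
    def univariate_panel(self) -> list[str]:
        return self.univariate.significant_proteins

    @property
    def multivariate_panel(self) -> list[str]:
        return list(self.trace.selected_set)

    @property
    def panel_overlap(self) -> set[str]:
        return set(self.univariate_panel) & set(self.multivariate_panel)

    def summary(self) -> dict:
        m = self.trace.final_cv.metrics
        return {
            "design": self.design.name,
            "n_samples": self.n_samples,
            "univariate_panel_size": len(self.univariate_panel),
            "multivariate_panel_size": len(self.multivariate_panel),
            "panel_overlap": len(self.panel_overlap),
            "best_n_lv": self.trace.best_n_lv,
            "cv_accuracy_pct": m.accuracy_pct,
            "cv_ner_pct": m.ner_pct,
            "fitting_accuracy_pct": self.trace.fitting_metrics.accuracy_pct,
            "seeds": self.seeds,
        }

    def write(self, directory) -> None:
        """Serialize all artifacts under one run directory."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.univariate.table.to_csv(d / "univariate.tsv", sep="\t")
        self.som_top_map.to_csv(d / "som_top_map.tsv", sep="\t")
        (d / "som_model.json").write_text(self.som.to_json())
        self.trace.write_tsv(d / "elimination_trace.tsv")
        coefficient_report(self.trace.final_model, self.trace.selected_set).to_csv(
            d / "selected_panel.tsv", sep="\t"
        )
        (d / "summary.json").write_text(json.dumps(self.summary(), indent=2))


def run_comparison(
    dataset: AbundanceDataset, design: ComparisonDesign, config: PipelineConfig
) -> ComparisonReport:
    """Run the full analysis chain for one two-class comparison."""
    sub, labels = subset_for_design(dataset, design)
    seeds = {s: _stage_seed(config.seed, design.name, s) for s in _STAGES}

    screen = ttest_fc_screen(
        sub.values,
        labels,
        protein_ids=sub.protein_ids,
        p_threshold=config.p_threshold,
        fc_upper=config.fc_upper,
        fc_lower=config.fc_lower,
    )

    scaled = autoscale(sub.values, sub.protein_ids)
    pca = pca_fit(scaled.values, n_components=config.pca_components)

    pooled = max(len(design.class_a), len(design.class_b)) > 1
    som_cfg = SOMConfig(
        rows=10 if pooled else 8,
        cols=10 if pooled else 8,
        epochs=300 if pooled else 200,
        seed=seeds["som"],
    )
    som = som_fit(scaled.values, som_cfg)
    occupancy = top_map(som, labels)
    weights_pca, neuron_classes = pca_on_som_weights(som, n_components=2, labels=labels)

    scheme = CVScheme(n_repeats=config.n_repeats, seed=seeds["selection"])
    groups = sub.metadata["animal_id"] + "/" + sub.metadata["timepoint"] if (
        config.replicate_aware_cv
    ) else None
    trace = backward_eliminate(
        sub.values,
        labels,
        scheme,
        max_lv=config.max_lv,
        variable_ids=sub.protein_ids,
        groups=None if groups is None else groups.to_numpy(),
    )

    return ComparisonReport(
        design=design,
        n_samples=sub.n_samples,
        univariate=screen,
        pca=pca,
        som=som,
        som_top_map=occupancy,
        som_weights_pca=weights_pca,
        som_neuron_classes=neuron_classes,
        trace=trace,
        protein_ids=list(sub.protein_ids),
        seeds=seeds,
    )


def run_all(
    dataset: AbundanceDataset,
    config: PipelineConfig,
    designs=DEFAULT_DESIGNS,
) -> dict[str, ComparisonReport]:
    """Run every comparison design; returns reports keyed by design name."""
    return {d.name: run_comparison(dataset, d, config) for d in designs}


def overlap_summary(reports: dict[str, ComparisonReport], panel: str = "multivariate") -> pd.DataFrame:
    """Cross-design overlap counts of the selected biomarker panels.

    One row per nonempty subset of designs with the size and membership
    of the literal set intersection (the numbers a Venn diagram would
    display).  ``panel`` chooses the multivariate or univariate panels.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports")
    universes = {frozenset(r.protein_ids) for r in reports.values()}
    if len(universes) != 1:
        raise ValueError("reports cover different protein universes")
    panels = {
        name: set(r.multivariate_panel if panel == "multivariate" else r.univariate_panel)
        for name, r in reports.items()
    }
    names = sorted(panels)
    rows = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inter = set.intersection(*(panels[c] for c in combo))
            rows.append(
                {
                    "designs": "&".join(combo),
                    "order": k,
                    "overlap": len(inter),
                    "members": ",".join(sorted(inter)),
                }
            )
    return pd.DataFrame(rows)
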