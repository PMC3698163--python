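"""Model/Results interface over the full fingerprint pipeline.

:class:`SpectralFingerprintModel` is constructed from a labelled
:class:`~specfinger.spectra.SpectraSet` plus the stage configurations;
``fit()`` runs preprocessing, feature scoring/selection, the
repeated-split ensemble and the aggregation, and returns a
:class:`SpectralFingerprintResults` carrying the estimates (sensitivity
and specificity over reliable calls), their bootstrap uncertainties, the
2x3 classification table, per-observation summaries, and diagnostics
(PCA projections, confidence plots).

Example
-------
>>> from specfinger import SyntheticCohortConfig, generate_cohort
>>> from specfinger.model import SpectralFingerprintModel
>>> cohort = generate_cohort(SyntheticCohortConfig(seed=1))
>>> res = SpectralFingerprintModel(cohort, master_seed=1).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import ensemble as ens
from . import features as feat
from . import pca as pca_mod
from .exceptions import CohortError
from .preprocess import FeatureMatrix, PreprocessConfig, preprocess_set
from .spectra import SpectraSet, SpectralRegion, read_spectra_table

#: default analysis windows: CH-stretch region and the fingerprint region,
#: skipping the water band near 3350 and the CO2 band near 2200 cm^-1
DEFAULT_REGIONS = (SpectralRegion(3150.0, 2750.0), SpectralRegion(1850.0, 750.0))


class SpectralFingerprintModel:
    """Disease-fingerprint classifier for labelled mid-IR spectra.

    Parameters
    ----------
    spectra
        Labelled cohort on a common wavenumber grid; samples labelled
        ``unknown`` are carried through preprocessing but excluded from
        training and metrics.
    regions
        Spectral windows analysed (default: 3150-2750 and
        1850-750 cm^-1).
    preprocess, ensemble_config
        Stage configurations; defaults follow the package's canonical
        pipeline (second derivative, 9-point Savitzky-Golay,
        per-spectrum region standardisation; 67 sessions, 3 hidden
        neurons).
    selection_method, fraction_of_max
        Feature ranking method (default ``bhattacharyya``) and the
        strict greater-than fraction-of-maximum threshold (default
        0.05).
    master_seed
        Overrides ``ensemble_config.master_seed`` when given.
    """

    def __init__(
        self,
        spectra: SpectraSet,
        regions: Sequence[SpectralRegion] = DEFAULT_REGIONS,
        preprocess: PreprocessConfig | None = None,
        selection_method: str = "bhattacharyya",
        fraction_of_max: float = 0.05,
        ensemble_config: ens.EnsembleConfig | None = None,
        master_seed: int | None = None,
    ):
        self.spectra = spectra
        self.regions = list(regions)
        self.preprocess = preprocess or PreprocessConfig()
        self.selection_method = selection_method
        self.fraction_of_max = fraction_of_max
        cfg = ensemble_config or ens.EnsembleConfig()
        if master_seed is not None:
            cfg = dataclasses.replace(cfg, master_seed=int(master_seed))
        self.ensemble_config = cfg

    @classmethod
    def from_csv(cls, path, label_column: str = "label", **kwargs) -> "SpectralFingerprintModel":
        """Build a model straight from a wide spectra CSV."""
        return cls(read_spectra_table(path, label_column=label_column), **kwargs)

    def fit(self) -> "SpectralFingerprintResults":
        """Run the full pipeline and return the results object."""
        fm = preprocess_set(self.spectra, self.regions, self.preprocess)
        lab = np.asarray(fm.labels, dtype=object)
        known = np.where(np.isin(lab, ["positive", "negative"]))[0]
        if known.size < 20:
            raise CohortError(
                f"only {known.size} labelled samples; ensemble needs a cohort"
            )
        Xk = fm.X[known]
        labk = lab[known]
        idsk = [fm.sample_ids[i] for i in known]

        scores = feat.score_wavenumbers(Xk, labk, self.selection_method)
        selection = feat.select_wavenumbers(scores, self.fraction_of_max)
        run = ens.run_ensemble(Xk[:, selection.selected], labk, self.ensemble_config)
        summaries = ens.summarize_observations(
            run.records, labk, self.ensemble_config, idsk
        )
        metrics = ens.evaluate_excluding_undefined(
            summaries,
            records=run.records,
            labels=labk,
            config=self.ensemble_config,
            sample_ids=idsk,
        )
        metrics.session_accuracy_mean = run.accuracy_mean
        metrics.session_accuracy_sd = run.accuracy_sd
        return SpectralFingerprintResults(
            model=self,
            feature_matrix=fm,
            scores=scores,
            selection=selection,
            run=run,
            summaries=summaries,
            metrics=metrics,
            trained_indices=known,
        )


@dataclass
class SpectralFingerprintResults:
    """Fitted-pipeline artefacts and classification metrics."""

    model: SpectralFingerprintModel
    feature_matrix: FeatureMatrix
    scores: feat.FeatureScores
    selection: feat.FeatureSelection
    run: ens.EnsembleRun
    summaries: list[ens.ObservationSummary]
    metrics: ens.MetricsReport
    trained_indices: np.ndarray

    # -- tabular accessors ---------------------------------------------------

    def observation_table(self) -> pd.DataFrame:
        """Per-sample mean, std, appearances and call."""
        return ens.summaries_frame(self.summaries)

    def feature_table(self) -> pd.DataFrame:
        """Per-wavenumber score with the selected flag."""
        df = self.scores.to_frame(self.feature_matrix.feature_map)
        df["selected"] = self.selection.mask(len(self.scores.scores))
        return df

    def classification_table(self) -> ens.ClassificationTable:
        return self.metrics.table

    # -- diagnostics ---------------------------------------------------------

    def _region_blocks_for_pca(self) -> dict:
        """Region -> feature block, fingerprint region first.

        The 1850-750 cm^-1 window separates the classes best, so it
        leads the diagnostic outputs.
        """
        blocks = self.feature_matrix.by_region()
        ordered = sorted(blocks.items(), key=lambda kv: kv[0].high)
        return {
            str(r): X[self.trained_indices] for r, X in ordered
        }

    def _trained_labels_ids(self):
        lab = [self.feature_matrix.labels[i] for i in self.trained_indices]
        ids = [self.feature_matrix.sample_ids[i] for i in self.trained_indices]
        return lab, ids

    def intra_class_pca(self, n_components: int = 4) -> pca_mod.PCAProjection:
        lab, ids = self._trained_labels_ids()
        return pca_mod.intra_class_projection(
            self._region_blocks_for_pca(), lab, n_components, ids
        )

    def inter_class_pca(self, n_components: int = 4) -> pca_mod.PCAProjection:
        lab, ids = self._trained_labels_ids()
        return pca_mod.inter_class_projection(
            self._region_blocks_for_pca(), lab, n_components, ids
        )

    # -- plots ---------------------------------------------------------------

    def plot_confidence(self, ax=None):
        """Sorted per-sample mean soft outputs with std bars.

        Samples are ordered by mean confidence; error bars crossing the
        decision level mark the undefined group.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        df = self.observation_table().sort_values("mean").reset_index(drop=True)
        level = self.model.ensemble_config.decision_level
        colors = df["call"].map(
            {"negative": "tab:green", "positive": "tab:red", "undefined": "tab:blue"}
        )
        ax.errorbar(
            np.arange(len(df)), df["mean"], yerr=df["std"],
            fmt="none", ecolor="0.7", elinewidth=0.6,
        )
        ax.scatter(np.arange(len(df)), df["mean"], s=8, c=colors)
        ax.axhline(level, color="k", lw=0.8, ls="--")
        ax.set_xlabel("sorted observations")
        ax.set_ylabel("mean soft output")
        ax.set_ylim(-0.05, 1.05)
        return ax

    def plot_selection(self, ax=None):
        """Score-vs-wavenumber map with the selection threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        df = self.feature_table()
        for _, sub in df.groupby("region_index"):
            ax.plot(sub["wavenumber"], sub["score"], lw=0.8, color="k")
            sel = sub[sub["selected"]]
            ax.scatter(sel["wavenumber"], sel["score"], s=6, color="tab:red")
        ax.axhline(self.selection.threshold, color="tab:blue", lw=0.8, ls=":")
        ax.invert_xaxis()
        ax.set_xlabel("wavenumber (cm$^{-1}$)")
        ax.set_ylabel(f"{self.scores.method} score")
        return ax

    # -- summary -------------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary."""
        m = self.metrics
        cfg = self.model.ensemble_config
        n_pos = sum(1 for s in self.summaries if s.true_label == "positive")
        n_neg = sum(1 for s in self.summaries if s.true_label == "negative")
        pm = lambda v, sd: (f"{v:.1f}%" if sd is None else f"{v:.1f}% +/- {sd:.1f}%")
        lines = [
            "Spectral fingerprint classification",
            "=" * 51,
            f"cohort: {n_pos} positive / {n_neg} negative samples",
            f"regions: {', '.join(str(r) for r in self.model.regions)}",
            f"features: {len(self.selection)} of {self.scores.scores.size} "
            f"selected ({self.scores.method}, >{self.selection.fraction_of_max:.0%} of max)",
            f"sessions: {cfg.n_sessions} x "
            f"{cfg.train_frac:.0%}/{cfg.val_frac:.0%}/{cfg.test_frac:.0%} split, "
            f"{cfg.hidden_neurons} hidden neurons, master_seed={cfg.master_seed}",
            f"session test accuracy: {100 * self.run.accuracy_mean:.1f}% "
            f"+/- {100 * self.run.accuracy_sd:.1f}%",
            "-" * 51,
            str(m.table),
            "-" * 51,
            f"sensitivity (excl. undefined): {pm(m.sensitivity, m.sensitivity_sd)}",
            f"specificity (excl. undefined): {pm(m.specificity, m.specificity_sd)}",
            f"undefined fraction: {100 * m.undefined_fraction:.1f}% "
            f"({m.n_summarised - m.n_reliable} of {m.n_summarised})",
        ]
        return "\n".join(lines)
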