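"""One-shot pipeline orchestration: cohort -> preprocess -> select ->
ensemble -> PCA -> report, fully seeded and logged.

:class:`RunConfig` bundles every stage configuration and serialises
to/from YAML; :func:`run_pipeline` executes the stages via
:class:`~specfinger.model.SpectralFingerprintModel` and writes the
artefacts (feature-score CSV, observation-summary CSV, classification
table, metrics JSON, PCA coordinates, plots, and a log capturing every
parameter and seed).  Reruns with the same config produce byte-identical
metrics JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ensemble import EnsembleConfig
from .exceptions import ConfigError
from .model import DEFAULT_REGIONS, SpectralFingerprintModel, SpectralFingerprintResults
from .preprocess import PreprocessConfig
from .spectra import SpectralRegion, parse_number, read_spectra_table, write_spectra_table
from .synthetic import SyntheticCohortConfig, generate_cohort


def _region_from_any(item) -> SpectralRegion:
    if isinstance(item, SpectralRegion):
        return item
    hi, lo = item
    if isinstance(hi, str):
        hi = parse_number(hi)
    if isinstance(lo, str):
        lo = parse_number(lo)
    return SpectralRegion(float(hi), float(lo))


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    ``input_path`` names a spectra CSV; when absent a synthetic cohort
    is generated from ``synthetic``.  Regions must be disjoint.
    """

    input_path: str | None = None
    label_column: str = "label"
    synthetic: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    regions: tuple = DEFAULT_REGIONS
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    selection_method: str = "bhattacharyya"
    fraction_of_max: float = 0.05
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    output_dir: str = "specfinger_run"

    def __post_init__(self):
        self.regions = tuple(_region_from_any(r) for r in self.regions)
        spans = sorted((r.low, r.high) for r in self.regions)
        for (l1, h1), (l2, h2) in zip(spans, spans[1:]):
            if l2 <= h1:
                raise ConfigError(f"regions overlap: [{l1},{h1}] and [{l2},{h2}]")

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "label_column": self.label_column,
            "synthetic": self.synthetic.to_dict(),
            "regions": [[r.high, r.low] for r in self.regions],
            "preprocess": dataclasses.asdict(self.preprocess),
            "selection_method": self.selection_method,
            "fraction_of_max": self.fraction_of_max,
            "ensemble": dataclasses.asdict(self.ensemble),
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            syn = dict(d["synthetic"])
            if "subcluster_weights" in syn:
                syn["subcluster_weights"] = tuple(syn["subcluster_weights"])
            d["synthetic"] = SyntheticCohortConfig(**syn)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "ensemble" in d and isinstance(d["ensemble"], dict):
            d["ensemble"] = EnsembleConfig(**d["ensemble"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Provenance hash over the analysis-relevant fields.

        The output directory does not influence results and is excluded,
        so reruns into different directories stay byte-identical.
        """
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_or_generate(config: RunConfig):
    if config.input_path:
        return read_spectra_table(config.input_path, config.label_column), "file"
    return generate_cohort(config.synthetic), "synthetic"


def run_pipeline(config: RunConfig, make_plots: bool = True) -> SpectralFingerprintResults:
    """Execute every stage and write all artefacts to ``output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    spectra, source = _load_or_generate(config)

    model = SpectralFingerprintModel(
        spectra,
        regions=config.regions,
        preprocess=config.preprocess,
        selection_method=config.selection_method,
        fraction_of_max=config.fraction_of_max,
        ensemble_config=config.ensemble,
    )
    results = model.fit()
    write_report(results, config, outdir, source, make_plots=make_plots)
    return results


def metrics_payload(results: SpectralFingerprintResults, config: RunConfig) -> dict:
    m = results.metrics.to_dict()
    m["selected_feature_count"] = int(len(results.selection))
    m["n_features_total"] = int(results.scores.scores.size)
    m["config_hash"] = config.config_hash()
    return m


def write_report(
    results: SpectralFingerprintResults,
    config: RunConfig,
    outdir: Path,
    source: str = "unspecified",
    make_plots: bool = True,
) -> None:
    """Write CSV/JSON/plot artefacts plus the human-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    results.feature_table().to_csv(outdir / "feature_scores.csv")
    results.observation_table().to_csv(outdir / "observations.csv", index=False)
    results.classification_table().counts.to_csv(outdir / "classification_table.csv")
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics_payload(results, config), fh, sort_keys=True, indent=2)
        fh.write("\n")
    results.intra_class_pca().to_frame().to_csv(outdir / "pca_intra.csv", index=False)
    results.inter_class_pca().to_frame().to_csv(outdir / "pca_inter.csv", index=False)

    m = results.metrics
    report = [
        results.summary(),
        "-" * 51,
        f"input source: {source}",
        f"config hash: {config.config_hash()}",
        f"selected features: {len(results.selection)}",
        f"undefined fraction: {100 * m.undefined_fraction:.1f}%",
    ]
    (outdir / "report.txt").write_text("\n".join(report) + "\n")

    log = ["pipeline run parameters (unset values are defaults):"]
    for key, val in sorted(config.to_dict().items()):
        log.append(f"  {key}: {val}")
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")

    if make_plots:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        ax = results.plot_confidence()
        ax.figure.savefig(outdir / "confidence.png", dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        ax = results.plot_selection()
        ax.figure.savefig(outdir / "selection_map.png", dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        for name, proj in [
            ("pca_intra", results.intra_class_pca()),
            ("pca_inter", results.inter_class_pca()),
        ]:
            fig, axp = plt.subplots(figsize=(5, 5))
            coords = proj.coordinates
            lab = proj.labels
            for cls, marker, color in [
                ("negative", "o", "tab:blue"),
                ("positive", "x", "tab:red"),
            ]:
                rows = [i for i, l in enumerate(lab) if l == cls]
                axp.scatter(
                    coords[rows, 0], coords[rows, 1],
                    marker=marker, s=18, color=color, label=cls,
                )
            axp.set_xlabel("PC1")
            axp.set_ylabel("PC2")
            axp.legend()
            fig.savefig(outdir / f"{name}.png", dpi=120, bbox_inches="tight")
            plt.close(fig)


def generate_to_csv(config: SyntheticCohortConfig, path) -> None:
    """Generate a cohort and write it as the canonical wide CSV."""
    write_spectra_table(generate_cohort(config), path)
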