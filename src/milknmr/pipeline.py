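"""End-to-end runs: simulate -> quantify -> bucket -> chemometrics -> report.

A :class:`RunConfig` (YAML-loadable) is validated up front, then
:func:`run_pipeline` executes the full analysis deterministically for the
configured seeds and writes every artifact (composition table, bucket
matrix, model and validation JSON, VIP table, figures, manifest) into a
run directory. :func:`make_report` renders a human-readable markdown
summary from a completed run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemometrics import (
    BucketMatrix, PLSDA, hotelling_outliers, marker_ttest, normalize_norcont,
    pareto_scale, pca,
)
from .library import IntegrationWindow, _check_disjoint, default_windows
from .processing import extract_integral_set, reference_shift
from .quantify import quantify
from .simulate import AcquisitionParams, CohortSpec, FattyAcidProfile, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "make_report", "demo_config"]

log = logging.getLogger(__name__)

_SPECIES_COLS = ("alpha_linolenic", "linoleic", "cla_ct", "cla_tt",
                 "caproleic", "ufa", "mufa", "sfa", "omega_ratio")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    outdir: str
    seed: int = 0
    n_per_class: object = 20
    lipid_scale: object = 1.0
    composition_jitter_sd: float = 0.08
    noise_sd: float = 0.05
    normalization: str = "norcont"
    n_components: int = 3
    n_segments: int = 7
    n_permutations: int = 100
    alpha: float = 0.05
    exclude_outliers: bool = True
    window_overrides: list | None = None
    make_figures: bool = True

    def __post_init__(self):
        if self.normalization not in ("unor", "norcont"):
            raise ValueError("normalization must be 'unor' or 'norcont'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_segments < 2 or self.n_components < 1:
            raise ValueError("invalid chemometrics parameters")
        # fail fast on overlapping user windows, before any computation
        self.windows()

    def windows(self) -> list[IntegrationWindow]:
        if not self.window_overrides:
            return default_windows()
        base = {w.name: w for w in default_windows()}
        for entry in self.window_overrides:
            w = IntegrationWindow(**entry)
            base[w.name] = w
        wins = list(base.values())
        _check_disjoint(wins)
        return wins

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_per_class=self.n_per_class, lipid_scale=self.lipid_scale,
            composition_jitter_sd=self.composition_jitter_sd, seed=self.seed)

    def acquisition_params(self) -> AcquisitionParams:
        return AcquisitionParams(noise_sd=self.noise_sd)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        return RunConfig(**yaml.safe_load(Path(path).read_text()))


def demo_config(outdir: str | Path, seed: int = 1, **overrides) -> RunConfig:
    """P-style demo design: 14 organic vs 16 conventional samples.

    Organic samples are semi-skimmed (lipid scale 1); half of the
    conventional samples carry twice the lipid amount (the 3% fat
    subgroup).
    """
    cfg = dict(
        outdir=str(outdir), seed=seed,
        n_per_class={"organic": 14, "conventional": 16},
        lipid_scale={"organic": 1.0,
                     "conventional": [2.0] * 8 + [1.0] * 8},
    )
    cfg.update(overrides)
    return RunConfig(**cfg)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def _config_hash(cfg: RunConfig) -> str:
    # hash the scientific configuration only, not where it is written
    payload = {k: v for k, v in cfg.as_dict().items() if k != "outdir"}
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _annotate_ppm(ppm: float, tol: float = 0.025) -> str:
    """Nearest assignment label within ``tol`` ppm of a bucket center."""
    from .library import assignment_table
    best, best_d = "", tol
    for a in assignment_table():
        d = abs(a.shift_ppm - ppm)
        if d < best_d:
            best, best_d = f"{a.group_label} ({a.species_id})", d
    return best


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setLevel(logging.INFO)
    root = logging.getLogger("milknmr")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        windows = config.windows()
        params = config.acquisition_params()
        spectra, labels, profiles = simulate_cohort(config.cohort_spec(), params)
        log.info("simulated %d samples (%s)", len(spectra),
                 ", ".join(f"{c}={labels.count(c)}" for c in sorted(set(labels))))

        # composition per sample
        comp_rows, truth_rows = [], []
        for i, (spec, prof) in enumerate(zip(spectra, profiles)):
            spec = reference_shift(spec)
            rep = quantify(extract_integral_set(spec, windows))
            comp_rows.append(rep.as_dict())
            truth_rows.append(prof.as_dict())
        sample_ids = [f"s{i:03d}" for i in range(len(spectra))]
        comp = pd.DataFrame(comp_rows, index=sample_ids)
        comp.insert(0, "class", labels)
        comp.to_csv(outdir / "composition.csv", index_label="sample_id")
        truth = pd.DataFrame(truth_rows, index=sample_ids)
        truth.insert(0, "class", labels)
        truth.to_csv(outdir / "ground_truth.csv", index_label="sample_id")

        # bucket matrices
        unor = BucketMatrix.from_spectra(spectra, labels, sample_ids=sample_ids)
        unor.to_csv(outdir / "bucket_matrix_unor.csv")
        matrix = normalize_norcont(unor) if config.normalization == "norcont" else unor
        if config.normalization == "norcont":
            matrix.to_csv(outdir / "bucket_matrix_norcont.csv")

        # PCA + one-shot outlier exclusion
        Xs, _, _ = pareto_scale(matrix.to_array())
        pcares = pca(Xs, n_components=2)
        outliers = np.zeros(len(labels), dtype=bool)
        if config.exclude_outliers:
            outliers = hotelling_outliers(pcares.scores, alpha=config.alpha)
            if outliers.any():
                dropped = [sample_ids[i] for i in np.nonzero(outliers)[0]]
                log.info("excluding %d outlier(s) at the %.0f%% limit: %s",
                         outliers.sum(), 100 * (1 - config.alpha), dropped)
                keep = ~outliers
                matrix = BucketMatrix(matrix.values.loc[keep],
                                      [l for l, k in zip(labels, keep) if k],
                                      normalization_tag=matrix.normalization_tag)
                Xs, _, _ = pareto_scale(matrix.to_array())
                pcares = pca(Xs, n_components=2)

        # PLS-DA + validation
        model = PLSDA(matrix.to_array(), matrix.class_labels,
                      n_components=config.n_components, scale="pareto")
        results = model.fit()
        report = results.cross_validate(n_segments=config.n_segments)
        perm = results.permutation_test(n_permutations=config.n_permutations,
                                        seed=config.seed,
                                        n_segments=config.n_segments)
        vip_scores = results.vip()

        classes = sorted(set(labels))
        ttests = {}
        for col in _SPECIES_COLS:
            g = [comp.loc[comp["class"] == c, col] for c in classes]
            t, p = marker_ttest(g[0], g[1])
            ttests[col] = {"t": t, "p": p}

        model_json = {
            "classes": results.classes,
            "n_components": results.n_components,
            "r2y": results.r2y,
            "r2y_per_component": results.r2y_per_component.tolist(),
            "pca_explained_variance_pct": pcares.explained_variance_pct.tolist(),
            "normalization": matrix.normalization_tag,
            "n_samples_fit": len(matrix.class_labels),
            "outliers_excluded": [sample_ids[i] for i in np.nonzero(outliers)[0]],
        }
        _dump_json(model_json, outdir / "model.json")
        _dump_json({**report.as_dict(), "permutation": perm.as_dict(),
                    "marker_ttests": ttests}, outdir / "validation.json")

        vip_df = pd.DataFrame({"ppm": matrix.centers, "vip": vip_scores})
        vip_df["annotation"] = [_annotate_ppm(p) for p in vip_df["ppm"]]
        vip_df.sort_values("vip", ascending=False).to_csv(
            outdir / "vip.csv", index=False)

        _dump_json({"package_version": __version__,
                    "config": config.as_dict(),
                    "config_hash": _config_hash(config)},
                   outdir / "manifest.json")

        if config.make_figures:
            _figures(outdir, spectra[0], pcares, results, matrix, vip_scores,
                     config.alpha)
        return outdir
    finally:
        root.removeHandler(handler)
        handler.close()


def _figures(outdir: Path, spectrum, pcares, results, matrix, vip_scores, alpha):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(spectrum.ppm, spectrum.intensity, lw=0.4)
    ax.set_xlim(7, -0.5)
    ax.set_xlabel("ppm")
    ax.set_ylabel("intensity")
    ax.set_title("example simulated spectrum")
    fig.savefig(outdir / "spectrum.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    T = results.x_scores
    labs = np.array(matrix.class_labels)
    for cls, color in zip(sorted(set(matrix.class_labels)), ("tab:green", "tab:orange")):
        m = labs == cls
        ax.scatter(T[m, 0], T[m, 1] if T.shape[1] > 1 else np.zeros(m.sum()),
                   label=cls, color=color)
    if T.shape[1] > 1:
        # 95% Hotelling ellipse on the first two score columns
        from scipy import stats as sstats
        n = T.shape[0]
        S = np.cov(T[:, :2], rowvar=False, ddof=1)
        lim = 2 * (n - 1) / (n - 2) * sstats.f.ppf(1 - alpha, 2, n - 2)
        theta = np.linspace(0, 2 * np.pi, 200)
        evals, evecs = np.linalg.eigh(S)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        ell = evecs @ (np.sqrt(evals * lim)[:, None] * circle)
        ax.plot(ell[0] + T[:, 0].mean(), ell[1] + T[:, 1].mean(),
                "k--", lw=0.8, label="95% T$^2$ limit")
    ax.set_xlabel("t1")
    ax.set_ylabel("t2")
    ax.legend()
    ax.set_title("PLS-DA scores")
    fig.savefig(outdir / "scores.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.vlines(matrix.centers, 0, vip_scores, lw=0.6)
    ax.axhline(1.0, color="r", lw=0.6, ls=":")
    ax.set_xlim(7, 0)
    ax.set_xlabel("ppm")
    ax.set_ylabel("VIP")
    fig.savefig(outdir / "vip.png", dpi=120, bbox_inches="tight")
    plt.close(fig)


def make_report(run_dir: str | Path) -> Path:
    """Render a markdown summary of a completed run; idempotent."""
    run_dir = Path(run_dir)
    needed = ["composition.csv", "model.json", "validation.json", "vip.csv",
              "manifest.json"]
    missing = [n for n in needed if not (run_dir / n).exists()]
    if missing:
        raise FileNotFoundError(f"run artifacts missing from {run_dir}: {missing}")

    comp = pd.read_csv(run_dir / "composition.csv", index_col="sample_id")
    model = json.loads((run_dir / "model.json").read_text())
    val = json.loads((run_dir / "validation.json").read_text())
    vip_df = pd.read_csv(run_dir / "vip.csv")
    manifest = json.loads((run_dir / "manifest.json").read_text())

    classes = sorted(comp["class"].unique())
    lines = [
        "# Milk lipid-fraction NMR analysis report",
        "",
        f"- package version: {manifest['package_version']}",
        f"- config hash: {manifest['config_hash']}",
        f"- normalization: {model['normalization']}",
        f"- samples fitted: {model['n_samples_fit']}"
        + (f" (excluded: {', '.join(model['outliers_excluded'])})"
           if model["outliers_excluded"] else ""),
        "",
        "## Composition (mol % of acyl chains, mean +/- sd)",
        "",
        "| quantity | " + " | ".join(classes) + " | t-test p |",
        "|---|" + "---|" * (len(classes) + 1),
    ]
    for col in _SPECIES_COLS:
        cells = []
        for cls in classes:
            v = comp.loc[comp["class"] == cls, col]
            cells.append(f"{v.mean():.2f} +/- {v.std(ddof=1):.2f}")
        p = val["marker_ttests"][col]["p"]
        lines.append(f"| {col} | " + " | ".join(cells) + f" | {p:.2e} |")

    lines += [
        "",
        "## Model and validation",
        "",
        f"- PCA PC1+PC2 explained variance: "
        f"{sum(model['pca_explained_variance_pct'][:2]):.1f}%",
        f"- PLS-DA R2Y (cum., {model['n_components']} components): {model['r2y']:.2f}",
        f"- Q2 ({val['n_segments']}-segment CV): {val['q2']:.2f}",
        f"- correct predictions: {val['pct_correct']:.1f}%",
        f"- Fisher exact p: {val['fisher_p']:.2e}",
        f"- permutation ({val['permutation']['n_permutations']} iterations): "
        f"Q2 intercept {val['permutation']['q2_intercept']:.2f}, "
        f"{'valid' if val['permutation']['valid'] else 'NOT valid'}",
        "",
        "## Top-10 VIP buckets",
        "",
        "| ppm | VIP | assignment |",
        "|---|---|---|",
    ]
    for _, row in vip_df.head(10).iterrows():
        lines.append(f"| {row['ppm']:.2f} | {row['vip']:.2f} | "
                     f"{row['annotation'] if isinstance(row['annotation'], str) else ''} |")

    out = run_dir / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out
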