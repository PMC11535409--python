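"""End-to-end pipeline driver: generate → morphometrics → force inference →
standardize → jsPCA → cluster → spatial statistics → render.

Every stochastic stage derives its seed from the config seed, so a persisted
config reproduces its outputs bit-identically; the output manifest records
SHA-256 hashes of every artifact plus the config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import forces, jspca, morphometrics, spatial, stats, synthetic
from .errors import SchemaError
from .io import write_feature_table
from .mesh import Tessellation

__all__ = [
    "PipelineConfig",
    "generate_cohort",
    "analyze_sample",
    "run_pipeline",
    "three_cluster_pipeline",
]


@dataclass
class PipelineConfig:
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    n_samples: int = 6
    n_cells: int = 1600
    domain_width: float = 300.0
    domain_height: float = 300.0
    notch_radius: float = 60.0
    lloyd_iters: int = 3
    base_cv: float = 0.1
    anisotropy_gain: float = 1.0
    alignment_gain: float = 0.6
    posterior_fraction: float = 0.4
    randomize_pattern: bool = False
    relax_tol: float = 1e-4
    feature_set: list = field(default_factory=lambda: list(spatial.DEFAULT_FEATURES))
    angle_reference: str = "ap"
    symmetrized: bool = False
    mu_grid: list = field(default_factory=lambda: list(forces.DEFAULT_MU_GRID))
    k: str | int = "auto"
    k_range: list = field(default_factory=lambda: [1, 2, 3, 4, 5])
    gmm_restarts: int = 20
    transfer_reference: str | None = None  # path to a prior run's models
    render: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def domain(self) -> synthetic.DomainSpec:
        return synthetic.DomainSpec(
            width=self.domain_width,
            height=self.domain_height,
            notch_radius=self.notch_radius,
        )

    def tension_model(self) -> synthetic.TensionModel:
        return synthetic.TensionModel(
            base_cv=self.base_cv,
            anisotropy_gain=self.anisotropy_gain,
            alignment_gain=self.alignment_gain,
        )


def generate_cohort(config: PipelineConfig):
    """Generate the cohort of equilibrated synthetic samples."""
    out = []
    for k in range(config.n_samples):
        tess, truth = synthetic.generate_sample(
            seed=config.seed + 1000 * (k + 1),
            n_cells=config.n_cells,
            domain=config.domain(),
            pattern=synthetic.dpw_pattern(
                config.domain(), posterior_fraction=config.posterior_fraction
            ),
            tension_model=config.tension_model(),
            lloyd_iters=config.lloyd_iters,
            tol=config.relax_tol,
            randomize=config.randomize_pattern,
            sample_id=f"e{k + 1}",
        )
        out.append((tess, truth))
    return out


def analyze_sample(tess: Tessellation, truth=None, mu_grid=forces.DEFAULT_MU_GRID):
    """Morphometrics + force inference for one sample.

    Returns (feature table with mechanical columns, adjacency graph).
    """
    feats = morphometrics.compute_features(tess)
    system = forces.build_balance_system(tess)
    sol = forces.solve_bayesian(system, mu_grid=mu_grid)
    feats = forces.attach_mechanics(feats, tess, sol)
    if truth is not None:
        feats["region_label"] = np.asarray(truth.region_label)
    graph = spatial.build_adjacency(tess)
    return feats, graph, sol


def three_cluster_pipeline(
    features: pd.DataFrame,
    graphs: dict,
    seed: int = 0,
    feature_set=None,
    angle_reference: str = "ap",
    k="auto",
    k_range=(1, 2, 3, 4, 5),
    restarts: int = 20,
):
    """jsPCA → GMM clustering on jsPC1 of a multi-sample feature table.

    ``graphs`` maps sample_id -> AdjacencyGraph.  Returns a dict with the
    jsPCA model, the cluster model, per-cell labels (aligned to ``features``),
    per-cell jsPC1 scores and the AIC table (None when k is fixed).
    """
    feature_set = list(feature_set or spatial.DEFAULT_FEATURES)
    table = spatial.prepare_analysis_table(features, feature_set, angle_reference)
    samples = spatial.standardize(table, feature_set)
    graph_list = [graphs[s.sample_id] for s in samples]
    model = jspca.fit_jspca(samples, graph_list)
    scores_by = {s.sample_id: jspca.project(s, model, 0) for s in samples}
    pooled = np.concatenate([scores_by[s.sample_id] for s in samples])

    aic_table = None
    if k == "auto":
        k, aic_table = cl.select_k(pooled, k_range=k_range, restarts=restarts,
                                   seed=seed)
    gmm = cl.fit_gmm(pooled, k=int(k), restarts=restarts, seed=seed)

    labels = np.empty(len(features), dtype=int)
    scores = np.empty(len(features), dtype=float)
    for s in samples:
        sel = (features["sample_id"] == s.sample_id).to_numpy()
        lab, _ = cl.assign(gmm, scores_by[s.sample_id])
        labels[sel] = lab
        scores[sel] = scores_by[s.sample_id]
    return {
        "jspca_model": model,
        "cluster_model": gmm,
        "labels": labels,
        "scores": scores,
        "aic_table": aic_table,
        "samples": samples,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full pipeline and write artifacts + manifest to ``out_dir``.

    Artifacts: per-sample meshes (JSON), pooled feature table with cluster
    labels (CSV), jsPCA model, cluster model, signatures, AIC table, spatial
    statistics report, and (optionally) rendered maps.  Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort(config)
    tables, graphs = [], {}
    for tess, truth in cohort:
        feats, graph, _sol = analyze_sample(tess, truth, mu_grid=config.mu_grid)
        tess.save(out / f"mesh_{tess.sample_id}.json", ground_truth=truth)
        tables.append(feats)
        graphs[tess.sample_id] = graph
    features = pd.concat(tables, ignore_index=True)

    if config.transfer_reference:
        ref = Path(config.transfer_reference)
        js_model = jspca.JsPCAModel.load(ref / "jspca_model.json")
        gmm = cl.ClusterModel.load(ref / "cluster_model.json")
        table = spatial.prepare_analysis_table(
            features, config.feature_set, config.angle_reference
        )
        samples = spatial.standardize(table, config.feature_set)
        labels = np.empty(len(features), dtype=int)
        scores = np.empty(len(features), dtype=float)
        for s in samples:
            sel = (features["sample_id"] == s.sample_id).to_numpy()
            sc = jspca.project(s, js_model, 0)
            labels[sel], _ = cl.assign(gmm, sc)
            scores[sel] = sc
        result = {"jspca_model": js_model, "cluster_model": gmm,
                  "labels": labels, "scores": scores, "aic_table": None}
    elif config.symmetrized:
        labels, js_model, gmm = cl.two_cluster_pipeline(
            features, graphs, seed=config.seed,
            feature_set=config.feature_set, restarts=config.gmm_restarts,
        )
        result = {"jspca_model": js_model, "cluster_model": gmm,
                  "labels": labels, "scores": None, "aic_table": None}
    else:
        result = three_cluster_pipeline(
            features,
            graphs,
            seed=config.seed,
            feature_set=config.feature_set,
            angle_reference=config.angle_reference,
            k=config.k,
            k_range=config.k_range,
            restarts=config.gmm_restarts,
        )

    features["cluster"] = result["labels"]
    if result.get("scores") is not None:
        features["jspc1_score"] = result["scores"]

    # spatial statistics
    ynorm = np.empty(len(features))
    for sid, grp in features.groupby("sample_id", sort=False):
        ynorm[grp.index.to_numpy()] = stats.normalize_ap(grp["centroid_y"].to_numpy())
    features["y_norm"] = ynorm

    report = {}
    labs = sorted(set(result["labels"].tolist()))
    if len(labs) >= 2:
        posterior_cluster = _posterior_cluster(features)
        report["posterior_cluster"] = int(posterior_cluster)
        for lab in labs:
            if lab == posterior_cluster:
                continue
            _, p = stats.cluster_position_test(
                features["y_norm"].to_numpy(),
                features["cluster"].to_numpy(),
                lab,
                posterior_cluster,
                side="A>B",
            )
            report[f"mw_p_cluster{lab}_anterior_of_cluster{posterior_cluster}"] = p
    oclass = stats.orientation_class(features["orientation"].to_numpy())
    for name in ("vertical", "horizontal"):
        sel = features.loc[oclass == name, "y_norm"].to_numpy()
        sel = sel[sel != 0]
        if sel.size >= 6:
            _, p = stats.symmetry_test(sel)
            report[f"wilcoxon_p_{name}_cells"] = p
    aniso = features.loc[features["stress_anisotropy"] < 0.3, "y_norm"].to_numpy()
    aniso = aniso[aniso != 0]
    if aniso.size >= 6:
        _, p = stats.symmetry_test(aniso)
        report["wilcoxon_p_anisotropic_cells"] = p

    # artifacts
    write_feature_table(features, out / "features.csv")
    result["jspca_model"].save(out / "jspca_model.json")
    result["cluster_model"].save(out / "cluster_model.json")
    sig = cl.cluster_signatures(features, result["labels"])
    sig.to_csv(out / "cluster_signatures.csv", index=False)
    if result.get("aic_table") is not None:
        result["aic_table"].to_csv(out / "aic_table.csv", index=False)
    with open(out / "stats_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    if config.render:
        from . import plots

        for tess, _truth in cohort:
            sel = features["sample_id"] == tess.sample_id
            fig = plots.cluster_map(tess, features.loc[sel, "cluster"].to_numpy(),
                                    title=f"clusters {tess.sample_id}")
            plots.save_figure(fig, out / f"cluster_map_{tess.sample_id}.svg")
            fig = plots.anisotropy_map(
                tess, features.loc[sel, "stress_anisotropy"].to_numpy(),
                title=f"anisotropy {tess.sample_id}")
            plots.save_figure(fig, out / f"anisotropy_map_{tess.sample_id}.svg")
        plots.save_figure(plots.loadings_heatmap(result["jspca_model"]),
                          out / "loadings_heatmap.svg")
        plots.save_figure(plots.eigenvalue_heatmap(result["jspca_model"]),
                          out / "eigenvalue_heatmap.svg")

    manifest = {
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _posterior_cluster(features: pd.DataFrame) -> int:
    """The cluster whose mean normalized AP coordinate is most posterior."""
    means = features.groupby("cluster")["y_norm"].mean()
    return int(means.idxmin())
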