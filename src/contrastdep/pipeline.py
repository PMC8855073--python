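"""End-to-end pipeline: simulate -> DE -> classify -> enrich -> report.

Each stage is deterministic given its inputs and the global seed; the run
writes TSV outputs per stage plus a JSON manifest of parameters and output
hashes, so two runs with identical config and seed are byte-identical.
Descriptive analytics (PCA over samples, volcano tables, Venn overlap counts,
dependence summary) are bundled in the report stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import io as cdio
from .de import DECallConfig, SampleDesign, normalize_counts, run_contrast
from .dependence import ClassifierConfig, build_contrast_pairs, classify_genes
from .enrichment import RIKEN_RULE, filter_genes, fisher_enrichment, read_gmt, write_gmt
from .simulate import SimulationConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    When ``counts`` / ``metadata`` paths are not given the run starts from
    the synthetic-data generator with ``sim``. ``restrict`` selects the
    family for the dependence tests: ``"de_a"`` (genes called DE in contrast
    A, the default) or ``"all"``.
    """

    outdir: str = "run"
    seed: int = 0
    sim: SimulationConfig | None = None
    counts: str | None = None
    metadata: str | None = None
    norm_method: str = "cpm_log2"
    prior_count: float = 0.5
    min_count: int = 10
    decall: DECallConfig = field(default_factory=DECallConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    restrict: str = "de_a"
    gmt: str | None = None
    n_top_genes: int = 500
    n_random_sets: int = 10


@dataclass
class ReportBundle:
    volcano: dict  # contrast name -> DataFrame(gene, logFC, minus_log10_p, call)
    pca_coords: pd.DataFrame
    pca_var_explained: np.ndarray
    venn: dict  # region label -> count
    dependence_summary: dict  # category -> {"n", "up", "down"}


def pca_embedding(
    values: pd.DataFrame, n_top_genes: int = 500, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the top-variance genes of a log-normalized matrix.

    Genes are ranked by variance across samples, the top ``n_top_genes`` are
    centered gene-wise (no scaling) and samples are projected onto the
    leading components. Returns per-sample coordinates and the fraction of
    variance per component.
    """
    n_samples = values.shape[1]
    if n_components >= n_samples:
        raise ValueError("n_components must be smaller than the number of samples")
    if n_top_genes > values.shape[0]:
        logger.warning(
            "requested %d top genes but only %d available; using all",
            n_top_genes, values.shape[0],
        )
        n_top_genes = values.shape[0]
    var = values.var(axis=1)
    top = var.sort_values(ascending=False, kind="mergesort").index[:n_top_genes]
    x = values.loc[top].to_numpy()
    x = x - x.mean(axis=1, keepdims=True)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x.T)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=values.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Gene, logFC, -log10 p and call per tested gene.

    p = 0 is floored at the smallest positive double so the display value
    stays finite.
    """
    if results.empty:
        raise ValueError("no results to tabulate")
    p = np.maximum(results["p"].to_numpy(), np.nextafter(0, 1))
    out = pd.DataFrame(
        {
            "logFC": results["beta"],
            "minus_log10_p": -np.log10(p),
            "call": results["call"] if "call" in results else "ns",
        },
        index=results.index,
    )
    return out


def venn_counts(de_sets: dict) -> dict:
    """Exclusive region counts for 2 or 3 named gene sets.

    Region labels join the member set names with ``&``; every gene of the
    union is counted in exactly one region.
    """
    names = list(de_sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn_counts supports 2 or 3 sets")
    sets = {k: set(v) for k, v in de_sets.items()}
    regions = {}
    for r in range(len(names), 0, -1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(*(sets[c] for c in names if c not in combo), set())
            regions["&".join(combo)] = len(inside - outside)
    return regions


def truth_gene_sets(
    truth: pd.DataFrame, rng: np.random.Generator, n_random: int = 10, set_size: int = 50
) -> dict:
    """Gene sets derived from planted truth labels plus random null sets.

    Used so the enrichment stage runs on synthetic data without an external
    collection: the planted dependent/independent sets should enrich in the
    DE query while the random sets should not.
    """
    sets = {}
    for label in ("dependent", "independent"):
        members = list(truth.index[truth["label"] == label])
        if members:
            sets[f"planted_{label}"] = members
    genes = np.asarray(truth.index)
    for i in range(n_random):
        sets[f"random_{i + 1:02d}"] = list(
            rng.choice(genes, size=min(set_size, len(genes)), replace=False)
        )
    return sets


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def run_pipeline(config: RunConfig, resume: bool = False) -> ReportBundle:
    """Execute the configured stages in order and write all outputs.

    With ``resume=True`` a stage whose output files already exist is loaded
    from disk instead of recomputed, so deleting one intermediate regenerates
    only the downstream stages.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # paths inside the manifest are relative to outdir so that two runs with
    # the same config and seed are byte-identical wherever they are written
    config_echo = _jsonable(dataclasses.replace(config, outdir="."))
    manifest = {"seed": config.seed, "config": config_echo, "stages": []}

    def _rel(p) -> str:
        p = Path(p)
        try:
            return str(p.relative_to(outdir))
        except ValueError:
            return p.name

    def record(stage: str, paths: dict, params: dict | None = None):
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {_rel(p): _sha256(Path(p)) for p in paths.values()},
                "params": _jsonable(params or {}),
            }
        )

    # --- stage: input data (simulate or load) -----------------------------
    truth = None
    if config.counts is not None:
        counts = cdio.read_counts(config.counts)
        meta = cdio.read_metadata(config.metadata)
        record("load", {"counts": config.counts, "metadata": config.metadata})
    else:
        sim_cfg = config.sim or SimulationConfig(seed=config.seed)
        sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)
        paths = {k: outdir / f"{k}.tsv" for k in ("counts", "metadata", "truth")}
        if resume and all(p.exists() for p in paths.values()):
            counts = cdio.read_counts(paths["counts"])
            meta = cdio.read_metadata(paths["metadata"])
            truth = cdio.read_results(paths["truth"])
        else:
            ds = generate_dataset(sim_cfg)
            ds.write(outdir)
            counts, meta, truth = ds.counts, ds.metadata, ds.truth
        record("simulate", {k: str(v) for k, v in paths.items()}, sim_cfg)

    groups = dict(zip(meta["sample_id"], meta["group"]))
    labels = list(dict.fromkeys(meta["group"]))
    if len(labels) != 4:
        raise ValueError(f"expected four groups, found {labels}")
    ctrl_a, ko_a, ctrl_b, ko_b = labels

    # --- stage: per-contrast DE -------------------------------------------
    results = {}
    for name, (ko, ctrl) in (("A", (ko_a, ctrl_a)), ("B", (ko_b, ctrl_b))):
        path = outdir / f"de_{name}.tsv"
        design = SampleDesign(groups=groups, contrast=(ko, ctrl))
        if resume and path.exists():
            results[name] = cdio.read_results(path)
        else:
            try:
                results[name] = run_contrast(
                    counts,
                    design,
                    norm_method=config.norm_method,
                    prior_count=config.prior_count,
                    min_count=config.min_count,
                    call_cfg=config.decall,
                )
            except Exception as exc:
                raise RuntimeError(f"stage de_{name} failed: {exc}") from exc
            cdio.write_table(results[name], path)
        record(f"de_{name}", {"results": str(path)}, {"contrast": [ko, ctrl]})

    # --- stage: dependence classification ---------------------------------
    cls_path = outdir / "classification.tsv"
    pairs = build_contrast_pairs(results["A"], results["B"])
    restrict = None
    if config.restrict == "de_a":
        restrict = tuple(results["A"].index[results["A"]["call"] != "ns"])
    cls_cfg = dataclasses.replace(config.classifier, restrict_to=restrict, seed=config.seed)
    if resume and cls_path.exists():
        calls = cdio.read_results(cls_path)
    else:
        calls = classify_genes(pairs, cls_cfg)
        cdio.write_table(calls, cls_path)
    record("classify", {"classification": str(cls_path)},
           {"factor": cls_cfg.dependence_factor, "fdr": cls_cfg.fdr_threshold,
            "restrict": config.restrict, "n_restrict": len(calls)})

    # --- stage: enrichment --------------------------------------------------
    enr_path = outdir / "enrichment.tsv"
    if config.gmt is not None:
        sets = read_gmt(config.gmt)
    elif truth is not None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        sets = truth_gene_sets(truth, rng, n_random=config.n_random_sets)
        write_gmt(sets, outdir / "gene_sets.gmt")
    else:
        sets = {}
    if sets:
        rules = [RIKEN_RULE, *map(re.escape, config.decall.exclude_genes)]
        universe = filter_genes(list(results["A"].index), rules)
        query = filter_genes(
            list(results["A"].index[results["A"]["call"] != "ns"]), rules
        )
        direction = results["A"]["call"].to_dict()
        if resume and enr_path.exists():
            enr = cdio.read_results(enr_path)
        else:
            enr = fisher_enrichment(query, universe, sets, direction_labels=direction)
            cdio.write_table(enr, enr_path, index_label="set")
        record("enrich", {"enrichment": str(enr_path)}, {"n_sets": len(sets)})

    # --- stage: report ------------------------------------------------------
    norm_all = normalize_counts(
        counts.loc[counts.sum(axis=1) > 0],
        method=config.norm_method,
        prior_count=config.prior_count,
    )
    coords, varexp = pca_embedding(norm_all.values, n_top_genes=config.n_top_genes)
    volcano = {name: volcano_table(res) for name, res in results.items()}
    venn = venn_counts(
        {
            "A": set(results["A"].index[results["A"]["call"] != "ns"]),
            "B": set(results["B"].index[results["B"]["call"] != "ns"]),
        }
    )
    summary = {}
    for cat in ("dependent", "independent", "neither"):
        rows = calls[calls["category"] == cat]
        summary[cat] = {
            "n": int(len(rows)),
            "up": int((rows["direction"] > 0).sum()),
            "down": int((rows["direction"] < 0).sum()),
        }
    report_paths = {"pca": outdir / "pca.tsv", "report": outdir / "report.json"}
    pca_out = coords.copy()
    cdio.write_table(pca_out, report_paths["pca"], index_label="sample_id")
    for name, tab in volcano.items():
        p = outdir / f"volcano_{name}.tsv"
        cdio.write_table(tab, p)
        report_paths[f"volcano_{name}"] = p
    report = {
        "pca_var_explained": [float(v) for v in varexp],
        "venn": venn,
        "dependence_summary": summary,
    }
    report_paths["report"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    record("report", {k: str(v) for k, v in report_paths.items()})

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return ReportBundle(
        volcano=volcano,
        pca_coords=coords,
        pca_var_explained=varexp,
        venn=venn,
        dependence_summary=summary,
    )


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a TOML file with [sim], [decall], [classifier] sections."""
    import tomllib

    from .simulate import config_from_dict

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    kwargs = {}
    for key in ("outdir", "seed", "counts", "metadata", "norm_method", "prior_count",
                "min_count", "restrict", "gmt", "n_top_genes", "n_random_sets"):
        if key in raw:
            kwargs[key] = raw[key]
    if "sim" in raw:
        kwargs["sim"] = config_from_dict(raw["sim"])
    if "decall" in raw:
        d = dict(raw["decall"])
        if "exclude_genes" in d:
            d["exclude_genes"] = tuple(d["exclude_genes"])
        kwargs["decall"] = DECallConfig(**d)
    if "classifier" in raw:
        kwargs["classifier"] = ClassifierConfig(**raw["classifier"])
    return RunConfig(**kwargs)
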