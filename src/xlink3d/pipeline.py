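"""End-to-end orchestration: annotate -> featurize -> label -> train -> rank.

One declarative :class:`RunConfig` drives a whole run; all randomness flows
from a single master seed through named substreams, so identical configs
produce byte-identical report bundles. Every output file carries the schema
version and a hash of the resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import crosslinks, features, fixtures
from .classify import (CVConfig, Dataset, DirectionConfig, PermutationConfig,
                       RFConfig, SMOTEConfig, crossval_auc, importance_report)
from .geometry import GeometryConfig, annotate
from .structure import read_structure

logger = logging.getLogger(__name__)

_SUBSTREAMS = ("cv", "smote", "perm", "direction", "simulate")


@dataclass
class RunConfig:
    task: str = "nucleotide"                  # or 'amino-acid'
    structures: list[str] = field(default_factory=list)
    instance_tables: dict[str, str] = field(default_factory=dict)
    aa_site_table: str | None = None          # TSV: accession chain seq_id crosslinked
    simulate: fixtures.TableSimSpec | None = None
    identity_blocks: bool = False
    cv_folds: int = 10
    n_bootstrap: int = 200
    n_permutations: int = 200
    rf_ntree: int | None = None               # None -> task preset
    rf_mtry: int | None = None
    direction_alpha: float | None = None
    direction_lam: float | None = None
    master_seed: int = 0
    outdir: str = "xlink3d-run"

    def seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.master_seed)
        children = ss.spawn(len(_SUBSTREAMS))
        return {name: int(c.generate_state(1)[0] % (2**31 - 1))
                for name, c in zip(_SUBSTREAMS, children)}

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True, indent=2, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("simulate"):
            sim = dict(d["simulate"])
            sim["informative"] = tuple(sim.get("informative", ()))
            if sim.get("feature_names"):
                sim["feature_names"] = tuple(sim["feature_names"])
            d["simulate"] = fixtures.TableSimSpec(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def _label_nucleotides(structure, table_path: str) -> dict[tuple, int]:
    """Map called ligand positions (0-based, 5'->3') onto RNA residues."""
    table = crosslinks.read_instance_table(table_path)
    calls = crosslinks.call_sites(table)
    nts = structure.rna_residues()
    labels = {}
    for _, row in calls.iterrows():
        pos = int(row["position"])
        if 0 <= pos < len(nts):
            labels[nts[pos].key] = int(row["crosslinked"])
        elif row["crosslinked"]:
            logger.info("%s: called position %d outside modeled ligand",
                        structure.accession, pos)
    return labels


def build_dataset(config: RunConfig) -> Dataset:
    """Assemble the labeled feature table the classifiers consume."""
    if config.simulate is not None:
        spec = dataclasses.replace(config.simulate,
                                   seed=config.seeds()["simulate"])
        return fixtures.simulate_feature_table(spec)

    frames, labels, groups = [], [], []
    aa_sites = None
    if config.aa_site_table:
        aa_sites = pd.read_csv(config.aa_site_table, sep="\t", comment="#")
    for gi, path in enumerate(config.structures):
        structure = read_structure(path)
        ann = annotate(structure, GeometryConfig())
        if config.task == "nucleotide":
            table = features.nucleotide_feature_table(structure, ann)
            site_labels = {}
            tpath = config.instance_tables.get(structure.accession)
            if tpath is None and len(config.instance_tables) == 1 \
                    and len(config.structures) == 1:
                tpath = next(iter(config.instance_tables.values()))
            if tpath:
                site_labels = _label_nucleotides(structure, tpath)
            keys = [(row["chain"], row["seq_id"], row["icode"] or "")
                    for _, row in table.iterrows()]
            lab = [site_labels.get((c, s, i if isinstance(i, str) else ""), 0)
                   for c, s, i in keys]
            contacting = table["n_contacting_residues"] > 0
        else:
            table = features.aa_feature_table(structure, ann)
            lab = np.zeros(len(table), dtype=int)
            if aa_sites is not None:
                marked = {(r["chain"], int(r["seq_id"]))
                          for _, r in aa_sites.iterrows()
                          if r.get("accession", structure.accession)
                          == structure.accession and int(r["crosslinked"])}
                lab = [int((row["chain"], int(row["seq_id"])) in marked)
                       for _, row in table.iterrows()]
            contacting = table["n_contacted_nucleotides"] > 0
        # sites without any protein/RNA contact are excluded from classification
        table = table[contacting.to_numpy()].reset_index(drop=True)
        lab = np.asarray(lab)[contacting.to_numpy()]
        frames.append(table)
        labels.append(lab)
        groups.append(np.full(len(table), gi))
    if not frames:
        raise ValueError("no structures and no simulation spec")
    big = pd.concat(frames, ignore_index=True)
    meta = big[features._META_COLS]
    X = big.drop(columns=features._META_COLS)
    return Dataset(X=X, y=np.concatenate(labels),
                   groups=np.concatenate(groups), meta=meta)


def _write_plots(outdir: Path, roc, report: pd.DataFrame, cfg_hash: str):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    plt.rcParams["svg.hashsalt"] = cfg_hash
    meta = {"Date": None}

    fig, ax = plt.subplots(figsize=(4, 4))
    if roc.pooled_scores is not None and getattr(roc, "_y", None) is not None:
        fpr, tpr, _ = roc_curve(roc._y, roc.pooled_scores)
        ax.plot(fpr, tpr, color="black")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    label = f"AUC = {roc.auc:.2f}"
    if roc.ci_lower is not None:
        label += f" [{roc.ci_lower:.2f}, {roc.ci_upper:.2f}]"
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(label, fontsize=10)
    fig.tight_layout()
    fig.savefig(outdir / "roc_curve.svg", metadata=meta)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    signed = report["mean_gini_decrease"] * report["direction_sign"].map(
        {"+": 1.0, "-": -1.0, "0": 0.0})
    ax.scatter(signed, report["robustness"], s=12, alpha=0.7)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_xlabel("signed Mean GiniDecrease")
    ax.set_ylabel("robustness $R_s$")
    fig.tight_layout()
    fig.savefig(outdir / "importance_scatter.svg", metadata=meta)
    plt.close(fig)


@dataclass
class ReportBundle:
    outdir: Path
    dataset: Dataset
    roc: object
    importance: pd.DataFrame
    paths: dict[str, Path]


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full workflow and write a report bundle to config.outdir."""
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.seeds()
    cfg_hash = config.config_hash()

    def stage(name, fn, *args, **kwargs):
        t = time.monotonic()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage=%s wall=%.2fs", name, time.monotonic() - t)
        return result

    dataset = stage("featurize+label", build_dataset, config)
    logger.info("stage=dataset rows=%d positives=%d features=%d",
                len(dataset.y), int(dataset.y.sum()), dataset.n_features)

    if config.rf_ntree is not None or config.rf_mtry is not None:
        rf = RFConfig(ntree=config.rf_ntree or 100, mtry=config.rf_mtry or 17)
    else:
        task = config.task if config.task in ("nucleotide", "amino-acid") \
            else "nucleotide"
        rf = RFConfig.for_task(task)
    cv = CVConfig(k=config.cv_folds, seed=seeds["cv"])
    smote = SMOTEConfig(seed=seeds["smote"])
    perm = PermutationConfig(n_permutations=config.n_permutations,
                             seed=seeds["perm"])
    direction = DirectionConfig(alpha=config.direction_alpha,
                                lam=config.direction_lam,
                                seed=seeds["direction"])

    roc = stage("train", crossval_auc, dataset, "rf", cv, smote, rf,
                config.n_bootstrap)
    roc._y = dataset.y
    report = stage("rank", importance_report, dataset, rf, smote, perm,
                   direction)

    paths = {}
    header = (f"# xlink3d-report config_hash={cfg_hash} "
              f"schema={'nt-v1' if config.task == 'nucleotide' else 'aa-v1'}\n")

    p = outdir / "config.json"
    p.write_text(config.to_json() + "\n")
    paths["config"] = p

    p = outdir / "features.tsv"
    table = dataset.X.copy()
    table.insert(0, "label", dataset.y)
    if dataset.meta is not None:
        table = pd.concat([dataset.meta.reset_index(drop=True), table], axis=1)
    with open(p, "w") as fh:
        fh.write(header)
        table.to_csv(fh, sep="\t", index=False)
    paths["features"] = p

    p = outdir / "roc.json"
    p.write_text(json.dumps({
        "config_hash": cfg_hash,
        "auc": roc.auc,
        "ci_lower": roc.ci_lower,
        "ci_upper": roc.ci_upper,
        "per_fold": roc.per_fold,
        "n_bootstrap": roc.n_bootstrap,
    }, indent=2, sort_keys=True) + "\n")
    paths["roc"] = p

    p = outdir / "importance.tsv"
    with open(p, "w") as fh:
        fh.write(header)
        report.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    paths["importance"] = p

    stage("plots", _write_plots, outdir, roc, report, cfg_hash)
    paths["roc_curve"] = outdir / "roc_curve.svg"
    paths["importance_scatter"] = outdir / "importance_scatter.svg"

    logger.info("pipeline done wall=%.2fs auc=%.3f", time.monotonic() - t0,
                roc.auc)
    return ReportBundle(outdir=outdir, dataset=dataset, roc=roc,
                        importance=report, paths=paths)
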