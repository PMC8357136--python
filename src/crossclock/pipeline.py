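"""End-to-end workflow: ingest -> filter -> normalize -> rank -> match -> evaluate.

`run_pipeline` executes the whole conserved-aging-gene workflow for a
two-species configuration and writes every intermediate table
(tab-delimited, UTF-8) plus a run manifest with per-stage gene counts,
output hashes and wall-clock times.  `demo` generates a synthetic
fixture with known ground truth, runs the pipeline on it and reports how
much of the planted conserved signal was recovered.

All randomness in a run derives from the single configured seed, and all
analysis artifacts are byte-reproducible under a fixed seed; only the
manifest differs across reruns (it records timings).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import ConfigError, CountDataset, filter_expressed, read_count_dataset
from .evaluate import EvalConfig, compare_feature_sets
from .normalize import log_counts, normalize_dataset, study_effect_score
from .orthologs import intersect_conserved, read_ortholog_table, resolve_best_match
from .ranking import correlate_with_age, top_k
from .simulate import demo_config, read_truth, simulate_dataset

__all__ = ["PipelineConfig", "PipelineResult", "RunManifest", "demo", "run_pipeline"]

N_NOISE_FEATURES = 50  # size of the negative-control gene set drawn from nulls


@dataclass
class PipelineConfig:
    counts_a: str = ""
    metadata_a: str = ""
    counts_b: str = ""
    metadata_b: str = ""
    orthologs: str = ""
    truth: str | None = None  # optional ground-truth table from the simulator
    output_dir: str = "crossclock_run"
    min_count: int = 10
    min_fraction: float = 0.5
    norm_method: str = "tmm"
    pseudocount: float = 0.5
    ranking_key: str = "absolute"
    ranking_method: str = "pearson"
    top_k: int = 1000
    eval_iterations: int = 100
    train_fraction: float = 0.75
    model: str = "xgboost"
    tasks: tuple[str, ...] = ("regression", "classification")
    seed: int = 0

    def validate(self) -> None:
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        for name in ("counts_a", "metadata_a", "counts_b", "metadata_b", "orthologs"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ConfigError(f"{name}: file {p!r} does not exist")
        from .models import available_models

        for task in self.tasks:
            if task not in ("regression", "classification"):
                raise ConfigError("tasks entries must be 'regression' or 'classification'")
            if self.model not in available_models(task):
                raise ConfigError(
                    f"model {self.model!r} is not available for {task}; "
                    f"choose one of {', '.join(available_models(task))}"
                )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field {sorted(unknown)[0]!r}")
        if "tasks" in raw:
            raw["tasks"] = tuple(raw["tasks"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["tasks"] = list(d["tasks"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list = field(default_factory=list)

    def add_stage(self, name, n_in, n_out, outputs: dict, seconds: float) -> None:
        self.stages.append(
            {
                "name": name,
                "n_in": int(n_in),
                "n_out": int(n_out),
                "outputs": {k: _sha256(v) for k, v in outputs.items()},
                "seconds": round(float(seconds), 3),
            }
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"version": self.version, "config": self.config, "stages": self.stages},
                fh,
                indent=2,
            )
            fh.write("\n")


@dataclass
class PipelineResult:
    conserved: pd.DataFrame
    rankings: dict
    top_lists: dict
    reports: dict  # (species, task) -> comparison DataFrame
    study_effect: pd.DataFrame
    manifest: RunManifest
    summary: dict
    output_dir: Path


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Context collecting wall-clock for one manifest entry."""

    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name
        self.n_in = self.n_out = 0
        self.outputs: dict = {}

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is None:
            self.manifest.add_stage(
                self.name, self.n_in, self.n_out, self.outputs, time.perf_counter() - self.t0
            )
        return False


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> Path:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g", **kwargs)
    return path


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage for both species and write all artifacts."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config={**asdict(cfg), "tasks": list(cfg.tasks)}, version=__version__)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(4, dtype=np.uint64) % (2**31)

    datasets: dict[str, CountDataset] = {}
    factors, matrices, rankings, top_lists = {}, {}, {}, {}
    effect_rows = []
    for tag in ("a", "b"):
        with _Stage(manifest, f"ingest_{tag}") as st:
            ds = read_count_dataset(getattr(cfg, f"counts_{tag}"), getattr(cfg, f"metadata_{tag}"))
            st.n_in = st.n_out = ds.n_genes
        with _Stage(manifest, f"filter_{tag}") as st:
            st.n_in = ds.n_genes
            ds = filter_expressed(ds, min_count=cfg.min_count, min_fraction=cfg.min_fraction)
            st.n_out = ds.n_genes
        datasets[tag] = ds
        with _Stage(manifest, f"normalize_{tag}") as st:
            st.n_in = st.n_out = ds.n_genes
            fac, nm = normalize_dataset(ds, method=cfg.norm_method, pseudocount=cfg.pseudocount)
            factors[tag], matrices[tag] = fac, nm
            path = _write_tsv(fac.to_frame(), out / f"factors_{tag}.tsv")
            st.outputs[f"factors_{tag}"] = path
            if ds.metadata["study_id"].nunique() >= 2:
                raw = log_counts(ds, pseudocount=cfg.pseudocount)
                effect_rows.append(
                    {
                        "species": tag,
                        "score_none": study_effect_score(raw, ds.metadata),
                        f"score_{cfg.norm_method}": study_effect_score(nm, ds.metadata),
                    }
                )
        with _Stage(manifest, f"rank_{tag}") as st:
            st.n_in = ds.n_genes
            tbl = correlate_with_age(nm, ds.ages, key=cfg.ranking_key, method=cfg.ranking_method)
            rankings[tag] = tbl
            top_lists[tag] = top_k(tbl, k=cfg.top_k, key=cfg.ranking_key)
            st.n_out = len(top_lists[tag])
            st.outputs[f"ranking_{tag}"] = _write_tsv(tbl, out / f"ranking_{tag}.tsv")

    effect = pd.DataFrame(effect_rows)
    if len(effect):
        _write_tsv(effect, out / "study_effect.tsv")

    with _Stage(manifest, "best_match") as st:
        ortho = read_ortholog_table(cfg.orthologs)
        st.n_in = len(ortho)
        best = resolve_best_match(ortho)
        st.n_out = len(best)
        st.outputs["best_match"] = _write_tsv(best, out / "best_match.tsv")

    with _Stage(manifest, "conserved") as st:
        st.n_in = len(best)
        conserved = intersect_conserved(
            top_lists["a"], top_lists["b"], best, rankings["a"], rankings["b"]
        )
        st.n_out = len(conserved)
        st.outputs["conserved_set"] = _write_tsv(conserved, out / "conserved_set.tsv")

    truth = read_truth(cfg.truth) if cfg.truth else None
    reports = {}
    summary: dict = {
        "n_genes_after_filter": {t: datasets[t].n_genes for t in ("a", "b")},
        "n_conserved": int(len(conserved)),
    }
    if truth is not None and truth.conserved_pairs:
        found = set(zip(conserved["gene_id_a"], conserved["gene_id_b"]))
        hits = found & set(truth.conserved_pairs)
        summary["conserved_recall"] = len(hits) / len(truth.conserved_pairs)
        summary["n_true_pairs"] = len(truth.conserved_pairs)

    for i, tag in enumerate(("a", "b")):
        ds = datasets[tag]
        sets = {
            "all": list(ds.gene_ids),
            "topk": list(top_lists[tag]),
            "conserved": list(conserved[f"gene_id_{tag}"]),
        }
        if not sets["conserved"]:
            sets.pop("conserved")
        if truth is not None:
            null_genes = sorted(set(ds.gene_ids) - truth.aging_genes(tag))
            pick = np.random.default_rng(int(seeds[2 + i]))
            if len(null_genes) > N_NOISE_FEATURES:
                idx = pick.choice(len(null_genes), size=N_NOISE_FEATURES, replace=False)
                null_genes = [null_genes[j] for j in sorted(idx)]
            sets["noise"] = null_genes
        for task in cfg.tasks:
            with _Stage(manifest, f"evaluate_{task}_{tag}") as st:
                st.n_in = ds.n_samples
                ecfg = EvalConfig(
                    n_iterations=cfg.eval_iterations,
                    train_fraction=cfg.train_fraction,
                    seed=int(seeds[i]),
                    task=task,
                    model=cfg.model,
                    pseudocount=cfg.pseudocount,
                )
                comp = compare_feature_sets(ds, factors[tag], sets, ecfg)
                reports[(tag, task)] = comp
                st.n_out = len(comp)
                st.outputs[f"{task}_{tag}"] = _write_tsv(comp, out / f"{task}_{tag}.tsv")
                if task == "classification":
                    for name, rep in comp.attrs["reports"].items():
                        cpath = out / f"confusion_{tag}_{name}.tsv"
                        rep.mean_confusion.to_csv(
                            cpath, sep="\t", index_label="true_group",
                            lineterminator="\n", float_format="%.10g",
                        )
                        st.outputs[f"confusion_{tag}_{name}"] = cpath
                for name, rep in comp.attrs["reports"].items():
                    key = "mean_r2" if task == "regression" else "mean_accuracy"
                    summary.setdefault(f"{task}_{tag}", {})[name] = rep.summary[key]

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.write(out / "manifest.json")
    return PipelineResult(
        conserved=conserved,
        rankings=rankings,
        top_lists=top_lists,
        reports=reports,
        study_effect=effect,
        manifest=manifest,
        summary=summary,
        output_dir=out,
    )


def demo(
    seed: int = 0,
    output_dir="crossclock_demo",
    n_iterations: int = 10,
    top_k: int = 1000,
    sim_overrides: dict | None = None,
    tasks: tuple[str, ...] = ("regression", "classification"),
    verbose: bool = True,
) -> PipelineResult:
    """Simulate a fixture, run the full pipeline on it, report recovery."""
    out = Path(output_dir)
    sim = simulate_dataset(demo_config(seed=seed, **(sim_overrides or {})))
    paths = sim.write(out / "fixture")
    cfg = PipelineConfig(
        counts_a=str(paths["species_a_counts"]),
        metadata_a=str(paths["species_a_metadata"]),
        counts_b=str(paths["species_b_counts"]),
        metadata_b=str(paths["species_b_metadata"]),
        orthologs=str(paths["orthologs"]),
        truth=str(paths["truth"]),
        output_dir=str(out / "run"),
        top_k=top_k,
        eval_iterations=n_iterations,
        tasks=tasks,
        seed=seed,
    )
    result = run_pipeline(cfg)
    if verbose:
        s = result.summary
        print(f"genes after filter: A={s['n_genes_after_filter']['a']} "
              f"B={s['n_genes_after_filter']['b']}")
        print(f"conserved pairs found: {s['n_conserved']}"
              + (f" (recall {s['conserved_recall']:.2f} of {s['n_true_pairs']} planted)"
                 if "conserved_recall" in s else ""))
        for key in sorted(k for k in s if k.startswith(("regression_", "classification_"))):
            metrics = ", ".join(f"{n}={v:.3f}" for n, v in s[key].items())
            print(f"{key}: {metrics}")
    return result
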