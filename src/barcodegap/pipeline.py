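"""End-to-end orchestration: one config in, a directory of artifacts out.

Stages: load-or-simulate -> sequence summary -> K2P matrix -> divergence
metrics -> barcoding-gap profile + rank-sum test -> leave-one-out
identification (both methods) -> per-species separability table -> NJ tree
with bootstrap supports (rooted when outgroups are flagged). Every artifact
is a plain-text TSV/JSON/Newick file under one run directory, and the whole
run is reproducible from the seed: identical config + seed produce
byte-identical tables (the run log carries the only timestamps).

Outgroup-flagged species participate only in the tree (where they root it);
all divergence, gap, identification and separability statistics are computed
on the ingroup.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .distance import pairwise_matrix
from .divergence import divergence_summary
from .gap_analysis import (
    gap_profile,
    plot_gap_profile,
    rank_sum_test,
    split_pair_distances,
    unique_sequence_species_pct,
)
from .identification import ScoringScheme, evaluate_loo, write_outcomes_tsv
from .phylogeny import bootstrap_nj, root_tree
from .seqio import read_labeled_fasta, summarize_sequences, write_labeled_fasta
from .simulate import GenusSimConfig, simulate_genus
from .taxongap import plot_gap_table, species_gap_table, write_gap_table_tsv

__all__ = ["PipelineError", "RunConfig", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage it occurred in."""


@dataclass
class RunConfig:
    """Declarative run description; exactly one of (fasta, simulate) is set."""

    fasta: str | None = None
    labels: str | None = None
    simulate: GenusSimConfig | None = None
    bin_width: float = 0.008
    below_threshold: float | None = None  # None -> observed intra maximum
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    bootstrap_replicates: int = 1000
    build_tree: bool = True
    identify_methods: tuple[str, ...] = ("nearest", "best_hit")
    plots: bool = False
    seed: int = 0
    outdir: str = "barcodegap_run"

    def validate(self) -> None:
        if (self.fasta is None) == (self.simulate is None):
            raise PipelineError(
                "exactly one of an input FASTA and a simulation config must be given"
            )
        if self.bin_width <= 0:
            raise PipelineError("bin_width must be > 0")
        if self.bootstrap_replicates < 0:
            raise PipelineError("bootstrap_replicates must be >= 0")
        for m in self.identify_methods:
            if m not in ("nearest", "best_hit"):
                raise PipelineError(f"unknown identification method {m!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        scoring = raw.pop("scoring", None)
        methods = raw.pop("identify_methods", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = GenusSimConfig(**sim)
        if scoring is not None:
            cfg.scoring = ScoringScheme(**scoring)
        if methods is not None:
            cfg.identify_methods = tuple(methods)
        return cfg


def _stage(name: str):
    class _Ctx:
        def __init__(self, log):
            self.log = log

        def __enter__(self):
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                self.log.append(f"[{name}] FAILED: {exc}")
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            self.log.append(f"[{name}] ok ({time.time() - self.t0:.2f}s)")
            return False

    return _Ctx


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run every stage and write artifacts under ``config.outdir``.

    Returns a dict of the in-memory results keyed by stage name.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"barcodegap {__version__} | python {platform.python_version()}",
        f"seed {config.seed}",
        f"started {time.strftime('%Y-%m-%d %H:%M:%S')}",
    ]
    results: dict[str, object] = {}

    with _stage("input")(log):
        if config.simulate is not None:
            sim = config.simulate
            aln, truth = simulate_genus(sim)
            write_labeled_fasta(aln, out / "simulated.fasta", out / "simulated_labels.tsv")
            truth.to_json(out / "simulation_truth.json")
            log.append(
                f"[input] simulated {len(aln)} sequences, "
                f"{len(aln.species)} species, seed {sim.seed}"
            )
        else:
            aln = read_labeled_fasta(config.fasta, config.labels)
            log.append(f"[input] read {len(aln)} sequences from {config.fasta}")
        if not aln.aligned:
            raise ValueError("input sequences are not aligned (unequal lengths)")
        results["alignment"] = aln

    ingroup = aln.ingroup()
    labels = aln.labels

    with _stage("summary")(log):
        summary = summarize_sequences(aln)
        results["summary"] = summary
        with open(out / "sequence_summary.json", "w") as fh:
            json.dump(summary.__dict__, fh, indent=2)
            fh.write("\n")

    with _stage("distances")(log):
        dm = pairwise_matrix(aln)
        dm.write_tsv(out / "distances.tsv")
        results["distance_matrix"] = dm

    with _stage("divergence")(log):
        div = divergence_summary(dm, labels, exclude=aln.outgroup_species)
        div.to_json(out / "divergence.json")
        with open(out / "divergence.tsv", "w") as fh:
            fh.write("measurement\tmean\tsd\n")
            for name, mean, sd in div.to_table():
                ms = "NA" if mean is None else f"{mean:.6f}"
                ss = "NA" if sd is None else f"{sd:.6f}"
                fh.write(f"{name}\t{ms}\t{ss}\n")
        results["divergence"] = div

    with _stage("gap")(log):
        intra, inter = split_pair_distances(dm, labels, exclude=aln.outgroup_species)
        profile = gap_profile(intra, inter, bin_width=config.bin_width,
                              below_threshold=config.below_threshold)
        profile.pct_species_unique_sequence = unique_sequence_species_pct(aln)
        profile.write_tsv(out / "gap_profile.tsv")
        profile.to_json(out / "gap_profile.json")
        if intra and inter:
            stat, p = rank_sum_test(inter, intra)
            with open(out / "gap_test.json", "w") as fh:
                json.dump({"test": "wilcoxon_rank_sum", "statistic": stat,
                           "p_two_sided": p, "n_inter": len(inter),
                           "n_intra": len(intra)}, fh, indent=2)
                fh.write("\n")
            results["gap_test"] = (stat, p)
        if config.plots:
            plot_gap_profile(profile, out / "gap_profile.png")
        results["gap_profile"] = profile

    with _stage("identification")(log):
        ing_dm = pairwise_matrix(ingroup) if len(ingroup) >= 2 else None
        rates = {}
        for method in config.identify_methods:
            sr, outcomes = evaluate_loo(ingroup, ing_dm, ingroup.labels, method,
                                        scoring=config.scoring)
            sr.to_json(out / f"identification_{method}.json")
            write_outcomes_tsv(outcomes, ingroup.labels, out / f"identification_{method}.tsv")
            rates[method] = sr
            log.append(
                f"[identification] {method}: {sr.pct_correct:.1f}% correct, "
                f"{sr.pct_ambiguous:.1f}% ambiguous, {sr.pct_incorrect:.1f}% incorrect"
            )
        results["identification"] = rates

    with _stage("taxongap")(log):
        table = species_gap_table(dm, labels, exclude=aln.outgroup_species)
        write_gap_table_tsv(table, out / "taxongap.tsv")
        if config.plots:
            plot_gap_table(table, out / "taxongap.png")
        results["taxongap"] = table

    if config.build_tree and len(aln) >= 3:
        with _stage("tree")(log):
            tree = bootstrap_nj(aln, n_replicates=config.bootstrap_replicates,
                                seed=config.seed)
            if aln.outgroup_species:
                tree = root_tree(tree, aln.outgroup_species, labels)
            tree.write_newick(out / "tree.nwk")
            results["tree"] = tree

    log.append(f"finished {time.strftime('%Y-%m-%d %H:%M:%S')}")
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return results
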