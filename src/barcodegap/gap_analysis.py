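"""Barcoding-gap assessment.

A usable barcode shows a *gap*: the distribution of between-species distances
sits clearly above the distribution of within-species distances. This module
splits the pairwise distances into the two distributions, profiles them on a
fixed-width histogram (default bin width 0.008 distance units), reports
overlap statistics (fraction of inter-specific pairs at zero distance and
below a threshold, by default the observed intra-specific maximum), and runs
a Wilcoxon rank-sum comparison of the two distributions.

Caveat: pairwise distances are statistically dependent (each sequence enters
many pairs), so the rank-sum p-value is reported in the conventional way of
the barcoding literature rather than as a dependence-aware test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .distance import DistanceMatrix
from .seqio import LabeledAlignment

__all__ = [
    "GapError",
    "GapProfile",
    "split_pair_distances",
    "gap_profile",
    "rank_sum_test",
    "unique_sequence_species_pct",
    "plot_gap_profile",
]


class GapError(ValueError):
    """Raised for unusable gap-profile input."""


@dataclass
class GapProfile:
    """Histogram + overlap statistics of intra vs inter distances.

    Bins are half-open ``[k*w, (k+1)*w)``; ``pct_inter_below`` counts
    inter-specific distances strictly below the threshold. The optional
    ``pct_species_unique_sequence`` is the percentage of multi-sample
    species whose haplotype set is disjoint from every other species'.
    """

    bin_width: float
    intra_counts: list[int]
    inter_counts: list[int]
    intra_range: tuple[float, float] | None
    inter_range: tuple[float, float] | None
    pct_inter_zero: float
    pct_inter_below: tuple[float, float]
    pct_species_unique_sequence: float | None = None

    @property
    def n_bins(self) -> int:
        return max(len(self.intra_counts), len(self.inter_counts))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    def write_tsv(self, path) -> None:
        """Per-bin table: bin start, bin end, intra count, inter count."""
        n = self.n_bins
        intra = self.intra_counts + [0] * (n - len(self.intra_counts))
        inter = self.inter_counts + [0] * (n - len(self.inter_counts))
        with open(path, "w") as fh:
            fh.write("bin_start\tbin_end\tintra_count\tinter_count\n")
            for k in range(n):
                fh.write(
                    f"{k * self.bin_width:.6f}\t{(k + 1) * self.bin_width:.6f}"
                    f"\t{intra[k]}\t{inter[k]}\n"
                )


def split_pair_distances(
    dm: DistanceMatrix, labels: Mapping[str, str], exclude: set[str] | None = None
) -> tuple[list[float], list[float]]:
    """Partition every unordered pair into (intra, inter) distance lists.

    Species in ``exclude`` (e.g. outgroups) contribute no pairs at all.
    """
    exclude = exclude or set()
    idx = [i for i, sid in enumerate(dm.ids) if labels[sid] not in exclude]
    intra: list[float] = []
    inter: list[float] = []
    for a in range(len(idx)):
        i = idx[a]
        for b in range(a + 1, len(idx)):
            j = idx[b]
            d = float(dm.values[i, j])
            (intra if labels[dm.ids[i]] == labels[dm.ids[j]] else inter).append(d)
    return intra, inter


def _bin_counts(values: Sequence[float], width: float) -> list[int]:
    if not values:
        return []
    ks = np.floor(np.asarray(values, dtype=float) / width).astype(int)
    counts = np.bincount(ks)
    return counts.tolist()


def gap_profile(
    intra: Sequence[float],
    inter: Sequence[float],
    bin_width: float = 0.008,
    below_threshold: float | None = None,
) -> GapProfile:
    """Profile the two distance distributions.

    ``below_threshold`` defaults to the observed intra-specific maximum (the
    natural overlap boundary); pass a value to fix it. Zero-distance pairs
    fall in bin 0 and are also reported as ``pct_inter_zero``.
    """
    if not intra and not inter:
        raise GapError("no distances to profile")
    if bin_width <= 0:
        raise GapError("bin_width must be > 0")
    intra_arr = np.asarray(intra, dtype=float)
    inter_arr = np.asarray(inter, dtype=float)
    if below_threshold is None:
        below_threshold = float(intra_arr.max()) if len(intra_arr) else 0.0
    if len(inter_arr):
        pct_zero = 100.0 * float((inter_arr == 0.0).sum()) / len(inter_arr)
        pct_below = 100.0 * float((inter_arr < below_threshold).sum()) / len(inter_arr)
        inter_range = (float(inter_arr.min()), float(inter_arr.max()))
    else:
        pct_zero, pct_below, inter_range = 0.0, 0.0, None
    intra_range = (float(intra_arr.min()), float(intra_arr.max())) if len(intra_arr) else None
    return GapProfile(
        bin_width=bin_width,
        intra_counts=_bin_counts(intra, bin_width),
        inter_counts=_bin_counts(inter, bin_width),
        intra_range=intra_range,
        inter_range=inter_range,
        pct_inter_zero=pct_zero,
        pct_inter_below=(float(below_threshold), pct_below),
    )


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration for small untied samples and the tie-corrected
    normal approximation otherwise. Returns ``(U statistic, two-sided p)``.
    If both samples are one identical constant, p = 1 with a warning.
    """
    if not len(x) or not len(y):
        raise GapError("rank_sum_test requires two non-empty samples")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if np.all(xa == ya[0]) and np.all(ya == ya[0]):
        warnings.warn("all values identical across both samples; p = 1")
        return float(len(xa) * len(ya) / 2.0), 1.0
    small = len(xa) <= 20 and len(ya) <= 20
    has_ties = len(np.unique(np.concatenate([xa, ya]))) < len(xa) + len(ya)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def unique_sequence_species_pct(aln: LabeledAlignment) -> float | None:
    """Percentage of multi-sample species with a haplotype set all their own.

    A species with >= 2 samples counts as "unique" when none of its distinct
    sequences occurs in any other species (gap characters stripped before
    comparison). Returns None when there is no multi-sample species.
    Outgroup-flagged species are ignored entirely.
    """
    ingroup = aln.ingroup()
    haplotypes: dict[str, set[str]] = {}
    for rec in ingroup.records:
        haplotypes.setdefault(rec.species, set()).add(rec.residues.replace("-", ""))
    counts: dict[str, int] = {}
    for rec in ingroup.records:
        counts[rec.species] = counts.get(rec.species, 0) + 1
    multi = [sp for sp, c in counts.items() if c >= 2]
    if not multi:
        return None
    n_unique = 0
    for sp in multi:
        others = set().union(*(h for s, h in haplotypes.items() if s != sp)) \
            if len(haplotypes) > 1 else set()
        if haplotypes[sp].isdisjoint(others):
            n_unique += 1
    return 100.0 * n_unique / len(multi)


def plot_gap_profile(profile: GapProfile, path) -> None:
    """Paired-bar histogram of the two distributions (relative frequencies)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = profile.n_bins
    intra = np.array(profile.intra_counts + [0] * (n - len(profile.intra_counts)), float)
    inter = np.array(profile.inter_counts + [0] * (n - len(profile.inter_counts)), float)
    if intra.sum():
        intra /= intra.sum()
    if inter.sum():
        inter /= inter.sum()
    centers = (np.arange(n) + 0.5) * profile.bin_width
    width = profile.bin_width * 0.42
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(centers - width / 2, intra, width=width, label="intra-specific")
    ax.bar(centers + width / 2, inter, width=width, label="inter-specific")
    ax.set_xlabel("K2P distance")
    ax.set_ylabel("relative frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
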