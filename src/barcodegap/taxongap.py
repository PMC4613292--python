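"""Per-species heterogeneity vs separability (TaxonGap-style table).

For each species, *heterogeneity* is the maximum within-species K2P distance
(0 for singletons, flagged) and *separability* the minimum distance to any
heterospecific sequence; a species is *separable* when separability exceeds
heterogeneity. The species attaining the minimum is the *closest relative*;
ties are all reported, sorted lexicographically. Species pairs with
separability exactly 0 — identical sequences across species — are the
marker's blind spots and are listed by ``inseparable_pairs``.

The original TaxonGap tool works on a similarity matrix; the K2P distance
matrix is used uniformly here for consistency with every other stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .distance import DistanceMatrix

__all__ = ["SpeciesGapRecord", "species_gap_table", "inseparable_pairs", "write_gap_table_tsv",
           "plot_gap_table"]


@dataclass(frozen=True)
class SpeciesGapRecord:
    """Heterogeneity/separability summary for one species."""

    species: str
    heterogeneity: float
    separability: float
    closest_relatives: tuple[str, ...]
    separable: bool
    singleton: bool

    @property
    def closest_relative(self) -> str:
        return self.closest_relatives[0]


def species_gap_table(dm: DistanceMatrix, labels: Mapping[str, str],
                      exclude: set[str] | None = None) -> list[SpeciesGapRecord]:
    """One record per (non-excluded) species, in first-appearance order."""
    exclude = exclude or set()
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(dm.ids):
        sp = labels[sid]
        if sp in exclude:
            continue
        if sp not in groups:
            order.append(sp)
        groups.setdefault(sp, []).append(i)
    if len(order) < 2:
        raise ValueError("need at least 2 species for a separability table")

    vals = dm.values
    records: list[SpeciesGapRecord] = []
    for sp in order:
        idx = np.asarray(groups[sp])
        if len(idx) >= 2:
            sub = vals[np.ix_(idx, idx)]
            het = float(sub[np.triu_indices(len(idx), k=1)].max())
            singleton = False
        else:
            het = 0.0
            singleton = True
        best = np.inf
        relatives: set[str] = set()
        for other in order:
            if other == sp:
                continue
            od = float(vals[np.ix_(idx, np.asarray(groups[other]))].min())
            if od < best - 1e-15:
                best = od
                relatives = {other}
            elif od <= best + 1e-15:
                relatives.add(other)
        records.append(SpeciesGapRecord(
            species=sp,
            heterogeneity=het,
            separability=float(best),
            closest_relatives=tuple(sorted(relatives)),
            separable=bool(best > het),
            singleton=singleton,
        ))
    return records


def inseparable_pairs(dm: DistanceMatrix, labels: Mapping[str, str],
                      exclude: set[str] | None = None) -> list[tuple[str, tuple[str, ...]]]:
    """Species whose minimum heterospecific distance is exactly zero.

    Returns ``(species, partner_species_tuple)`` for each affected species;
    partners are the heterospecific species sharing an identical sequence.
    """
    out: list[tuple[str, tuple[str, ...]]] = []
    for rec in species_gap_table(dm, labels, exclude):
        if rec.separability == 0.0:
            partners = tuple(r for r in rec.closest_relatives)
            out.append((rec.species, partners))
    return out


def write_gap_table_tsv(records: list[SpeciesGapRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("species\theterogeneity\tseparability\tclosest_relative\tseparable\tsingleton\n")
        for r in records:
            fh.write(
                f"{r.species}\t{r.heterogeneity:.6f}\t{r.separability:.6f}"
                f"\t{','.join(r.closest_relatives)}\t{'yes' if r.separable else 'no'}"
                f"\t{'yes' if r.singleton else 'no'}\n"
            )


def plot_gap_table(records: list[SpeciesGapRecord], path) -> None:
    """Horizontal paired bars: heterogeneity (light) vs separability (dark)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(records)
    y = np.arange(n)
    fig, ax = plt.subplots(figsize=(7, max(3, 0.22 * n)))
    ax.barh(y + 0.2, [r.heterogeneity for r in records], height=0.38,
            color="lightgray", label="heterogeneity (max intra)")
    ax.barh(y - 0.2, [r.separability for r in records], height=0.38,
            color="dimgray", label="separability (min inter)")
    ax.set_yticks(y, [r.species for r in records], fontsize=6)
    ax.invert_yaxis()
    ax.set_xlabel("K2P distance")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
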