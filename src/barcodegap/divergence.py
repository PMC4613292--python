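"""The six classical barcode divergence metrics.

Three inter-specific metrics and three intra-specific ones, following the
convention of the ITS2-barcoding literature:

* all inter-specific distance — mean over every heterospecific sequence pair;
* theta prime — per species, the mean distance to all heterospecific
  sequences, averaged (unweighted) across species;
* minimum inter-specific distance — per species, the minimum distance to any
  heterospecific sequence, averaged across species;
* all intra-specific distance — mean over every conspecific pair;
* theta — per species, the mean conspecific distance, averaged across
  multi-sample species;
* coalescent depth — per species, the maximum conspecific distance, averaged
  across multi-sample species.

"All" metrics pool pairs; the others average a per-species statistic, which
is why the minimum inter-specific distance can exceed the all-inter mean.
Dispersions are population standard deviations over the pooled items (pairs
or species). Species with a single sample contribute to the inter metrics
but are excluded from all three intra metrics. Outgroup species can be
excluded via ``exclude``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np

from .distance import DistanceMatrix

__all__ = ["DivergenceError", "DivergenceSummary", "divergence_summary", "per_species_stats"]


class DivergenceError(ValueError):
    """Raised when a metric set cannot be computed at all."""


@dataclass(frozen=True)
class DivergenceSummary:
    """Mean +/- SD for the six metrics (K2P units); None when undefined.

    Intra metrics are None when no species has >= 2 samples; inter metrics
    are None with fewer than 2 species.
    """

    all_inter_mean: float | None
    all_inter_sd: float | None
    theta_prime_mean: float | None
    theta_prime_sd: float | None
    min_inter_mean: float | None
    min_inter_sd: float | None
    all_intra_mean: float | None
    all_intra_sd: float | None
    theta_mean: float | None
    theta_sd: float | None
    coalescent_depth_mean: float | None
    coalescent_depth_sd: float | None
    n_species_total: int
    n_species_multi: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    def to_table(self) -> list[tuple[str, float | None, float | None]]:
        """(metric, mean, sd) rows in the conventional report order."""
        return [
            ("All inter-specific distance", self.all_inter_mean, self.all_inter_sd),
            ("Theta prime", self.theta_prime_mean, self.theta_prime_sd),
            ("The minimum inter-specific distance", self.min_inter_mean, self.min_inter_sd),
            ("All intra-specific distance", self.all_intra_mean, self.all_intra_sd),
            ("Theta", self.theta_mean, self.theta_sd),
            ("Coalescent depth", self.coalescent_depth_mean, self.coalescent_depth_sd),
        ]


def _mean_sd(values: Iterable[float]) -> tuple[float, float]:
    arr = np.asarray(list(values), dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))


def _species_groups(dm: DistanceMatrix, labels: Mapping[str, str],
                    exclude: set[str]) -> dict[str, np.ndarray]:
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(dm.ids):
        if sid not in labels:
            raise DivergenceError(f"no species label for sequence {sid!r}")
        sp = labels[sid]
        if sp in exclude:
            continue
        groups.setdefault(sp, []).append(i)
    return {sp: np.asarray(idx) for sp, idx in groups.items()}


def per_species_stats(dm: DistanceMatrix, labels: Mapping[str, str],
                      exclude: set[str] | None = None) -> dict[str, dict[str, float | None]]:
    """Per-species building blocks of the six metrics.

    For each species: ``intra_mean``/``intra_max`` over conspecific pairs
    (None for singletons), ``hetero_mean``/``hetero_min`` over distances to
    every heterospecific sequence (None if the species stands alone).
    """
    groups = _species_groups(dm, labels, exclude or set())
    if not groups:
        raise DivergenceError("no species left after exclusions")
    vals = dm.values
    if np.isnan(vals).any():
        raise DivergenceError("distance matrix contains missing entries")
    out: dict[str, dict[str, float | None]] = {}
    all_idx = np.concatenate(list(groups.values()))
    for sp, idx in groups.items():
        rec: dict[str, float | None] = {}
        if len(idx) >= 2:
            sub = vals[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            pairs = sub[iu]
            rec["intra_mean"] = float(pairs.mean())
            rec["intra_max"] = float(pairs.max())
        else:
            rec["intra_mean"] = None
            rec["intra_max"] = None
        other = np.setdiff1d(all_idx, idx)
        if len(other):
            het = vals[np.ix_(idx, other)]
            rec["hetero_mean"] = float(het.mean())
            rec["hetero_min"] = float(het.min())
        else:
            rec["hetero_mean"] = None
            rec["hetero_min"] = None
        out[sp] = rec
    return out


def divergence_summary(dm: DistanceMatrix, labels: Mapping[str, str],
                       exclude: set[str] | None = None) -> DivergenceSummary:
    """Compute the six divergence metrics from a complete distance matrix.

    ``labels`` maps sequence id -> species; ``exclude`` drops species (e.g.
    outgroups) entirely. Undefined metric families are reported as None,
    never as zero.
    """
    exclude = exclude or set()
    groups = _species_groups(dm, labels, exclude)
    stats = per_species_stats(dm, labels, exclude)
    vals = dm.values

    species = list(groups)
    multi = [sp for sp in species if len(groups[sp]) >= 2]

    inter_pairs: list[float] = []
    intra_pairs: list[float] = []
    for a in range(len(species)):
        ia = groups[species[a]]
        sub = vals[np.ix_(ia, ia)]
        iu = np.triu_indices(len(ia), k=1)
        intra_pairs.extend(sub[iu].tolist())
        for b in range(a + 1, len(species)):
            ib = groups[species[b]]
            inter_pairs.extend(vals[np.ix_(ia, ib)].ravel().tolist())

    if len(species) >= 2:
        all_inter = _mean_sd(inter_pairs)
        theta_prime = _mean_sd(stats[sp]["hetero_mean"] for sp in species)
        min_inter = _mean_sd(stats[sp]["hetero_min"] for sp in species)
    else:
        all_inter = theta_prime = min_inter = (None, None)

    if multi:
        all_intra = _mean_sd(intra_pairs)
        theta = _mean_sd(stats[sp]["intra_mean"] for sp in multi)
        depth = _mean_sd(stats[sp]["intra_max"] for sp in multi)
    else:
        all_intra = theta = depth = (None, None)

    return DivergenceSummary(
        all_inter_mean=all_inter[0], all_inter_sd=all_inter[1],
        theta_prime_mean=theta_prime[0], theta_prime_sd=theta_prime[1],
        min_inter_mean=min_inter[0], min_inter_sd=min_inter[1],
        all_intra_mean=all_intra[0], all_intra_sd=all_intra[1],
        theta_mean=theta[0], theta_sd=theta[1],
        coalescent_depth_mean=depth[0], coalescent_depth_sd=depth[1],
        n_species_total=len(species),
        n_species_multi=len(multi),
    )
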