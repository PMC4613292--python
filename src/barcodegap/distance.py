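"""Kimura 2-parameter distances with pairwise deletion.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions.
Over the sites where both sequences carry an unambiguous nucleotide, let P be
the proportion of sites differing by a transition and Q the proportion
differing by a transversion; the distance in expected substitutions/site is

    d = -(1/2) * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Columns containing a gap, N, or any other non-ACGT symbol in either member of
a pair are excluded for that pair only (pairwise deletion), matching the
default gap treatment of mainstream distance software. When the argument of a
logarithm is non-positive the sequences are saturated and the distance is
undefined; the default policy is a hard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import LabeledAlignment

__all__ = [
    "DistanceError",
    "SaturationError",
    "DistanceMatrix",
    "k2p_distance",
    "k2p_from_proportions",
    "k2p_variance",
    "pairwise_matrix",
    "encode_alignment",
]

# A,G purines get codes 0,1 ; C,T pyrimidines 2,3 : a substitution is a
# transition iff the codes differ but agree on bit 1 (same base class).
_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"AGCT", (0, 1, 2, 3)):
    _CODE[_b] = _c
_INVALID = 255


class DistanceError(ValueError):
    """Raised for invalid distance computations (e.g. no comparable sites)."""


class SaturationError(DistanceError):
    """Raised when P, Q put the K2P log arguments at or below zero."""


def encode_alignment(aln: LabeledAlignment) -> np.ndarray:
    """Encode an alignment as an (n_sequences, n_sites) uint8 matrix.

    A=0, G=1, C=2, T=3; gaps and ambiguity codes map to 255 (ignored sites).
    """
    if not aln.aligned:
        raise DistanceError("alignment required: sequences have unequal lengths")
    rows = [np.frombuffer(r.residues.encode("ascii"), dtype=np.uint8) for r in aln.records]
    return _CODE[np.vstack(rows)]


def k2p_from_proportions(p: float, q: float) -> float:
    """K2P distance from transition/transversion proportions P and Q."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"saturation: distance undefined for P={p:.6g}, Q={q:.6g}"
        )
    return float(-0.5 * np.log(w1 * np.sqrt(w2))) + 0.0  # +0.0 normalizes -0.0


def k2p_variance(p: float, q: float, n_sites: int) -> float:
    """Sampling variance of the K2P distance estimate (delta method).

    Uses c1 = 1/(1-2P-Q), c2 = 1/(1-2Q), c3 = (c1+c2)/2:
    V = [c1^2 P + c3^2 Q - (c1 P + c3 Q)^2] / n_sites.
    """
    c1 = 1.0 / (1.0 - 2.0 * p - q)
    c2 = 1.0 / (1.0 - 2.0 * q)
    c3 = 0.5 * (c1 + c2)
    return (c1 * c1 * p + c3 * c3 * q - (c1 * p + c3 * q) ** 2) / n_sites


def _pq_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    valid = (a != _INVALID) & (b != _INVALID)
    n = int(valid.sum())
    diff = valid & (a != b)
    transitions = int((diff & ((a >> 1) == (b >> 1))).sum())
    transversions = int(diff.sum()) - transitions
    return transitions, transversions, n


def k2p_distance(a: str, b: str) -> tuple[float, int]:
    """K2P distance between two aligned residue strings.

    Returns ``(distance, comparable_sites)`` where comparable sites are those
    with an unambiguous nucleotide in both sequences (pairwise deletion).

    Raises
    ------
    DistanceError
        On unequal lengths or zero comparable sites.
    SaturationError
        When the distance is undefined for the observed P, Q.
    """
    if len(a) != len(b):
        raise DistanceError(f"unequal sequence lengths: {len(a)} vs {len(b)}")
    ea = _CODE[np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)]
    eb = _CODE[np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)]
    ts, tv, n = _pq_counts(ea, eb)
    if n == 0:
        raise DistanceError("no comparable sites (all columns gapped or ambiguous)")
    return float(k2p_from_proportions(ts / n, tv / n)), n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P matrix keyed by sequence id.

    ``values[i, j]`` is the distance (NaN where the permissive saturation
    policy recorded a pair as missing); ``comparable_sites[i, j]`` the number
    of sites it was computed on.
    """

    ids: list[str]
    values: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n) or self.comparable_sites.shape != (n, n):
            raise DistanceError("matrix shape does not match id count")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, seq_id: str) -> int:
        return self.ids.index(seq_id)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.index(id_a), self.index(id_b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path, decimals: int = 6) -> None:
        """Square-matrix TSV with ids as row/column headers."""
        self.to_dataframe().round(decimals).to_csv(path, sep="\t", float_format=f"%.{decimals}f")

    def write_phylip(self, path) -> None:
        """PHYLIP square distance format (relaxed names)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(f"{v:.6f}" for v in self.values[i])
                fh.write(f"{sid}  {row}\n")

    def to_skbio(self):
        """Convert to an skbio DistanceMatrix (requires no missing entries)."""
        from skbio import DistanceMatrix as SkbioDM

        return SkbioDM(self.values, self.ids)


def pairwise_matrix(aln: LabeledAlignment, on_saturation: str = "fail") -> DistanceMatrix:
    """All-pairs K2P distance matrix for an aligned dataset.

    Parameters
    ----------
    aln:
        Labeled alignment with ``aligned=True`` and at least two records.
    on_saturation:
        ``"fail"`` (default) raises on any saturated pair; ``"missing"``
        records the pair as NaN with a warning, for exploratory use.
    """
    if len(aln) < 2:
        raise DistanceError("need at least 2 sequences for a distance matrix")
    if on_saturation not in ("fail", "missing"):
        raise ValueError("on_saturation must be 'fail' or 'missing'")
    enc = encode_alignment(aln)
    n = enc.shape[0]
    values = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(sites, (enc != _INVALID).sum(axis=1))
    valid = enc != _INVALID
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        nn = both.sum(axis=1)
        diff = both & (enc[i] != enc[i + 1 :])
        ts = (diff & ((enc[i] >> 1) == (enc[i + 1 :] >> 1))).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        for k, j in enumerate(range(i + 1, n)):
            if nn[k] == 0:
                raise DistanceError(
                    f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            try:
                d = k2p_from_proportions(ts[k] / nn[k], tv[k] / nn[k])
            except SaturationError:
                if on_saturation == "fail":
                    raise SaturationError(
                        f"saturation: distance undefined between "
                        f"{aln.ids[i]!r} and {aln.ids[j]!r}"
                    ) from None
                warnings.warn(
                    f"saturated pair ({aln.ids[i]}, {aln.ids[j]}) recorded as missing"
                )
                d = np.nan
            values[i, j] = values[j, i] = d
            sites[i, j] = sites[j, i] = nn[k]
    return DistanceMatrix(list(aln.ids), values, sites)
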