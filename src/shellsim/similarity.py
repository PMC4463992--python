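"""The nine-parameter radial-shell similarity score.

A structure is binned into concentric shells around its geometric center
(default: ten shells with boundaries at 10, 20, ..., 80, 100 length units,
the last shell open-ended).  An ordered pair of structures is scored on nine
parameters:

==  =======================================
S1  shell-density similarity (weighted sum over shells)
S2  total atom count
S3  residue count
S4  residue-type count (among the 20 standard amino acids)
S5  carbon proportion
S6  nitrogen proportion
S7  oxygen proportion
S8  phosphorus shell position
S9  sulfur shell position
==  =======================================

S2-S7 use the relative-difference form ``1 - |n1 - n2| / n1`` with the query
structure's value in the denominator; the score is deliberately asymmetric
and unclamped, so values below zero are possible (and occur for dissimilar
pairs).  S8/S9 use a positional rule: same shell 1.0, adjacent shells 0.8,
otherwise 0.  The overall score is a plain dot product with a nine-weight
vector; the packaged default weights were fitted by back-propagation on
labelled protein pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from shellsim.structure_io import ProteinStructure, radial_distances

__all__ = [
    "LayerScheme",
    "LayerProfile",
    "DEFAULT_LAYER_SCHEME",
    "ParameterSimilarityVector",
    "WeightVector",
    "STANDARD_AMINO_ACIDS",
    "layer_profile",
    "per_layer_similarity",
    "layer_weights",
    "density_similarity",
    "scalar_similarity",
    "count_atoms",
    "count_residues",
    "count_residue_types",
    "element_fraction",
    "element_position_similarity",
    "parameter_vector",
    "overall_similarity",
    "rank_reference_proteins",
]

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


@dataclass(frozen=True)
class LayerScheme:
    """Concentric-shell binning: shell i is ``[b[i-1], b[i])``, last open-ended."""

    breakpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        bp = self.breakpoints
        if len(bp) < 1 or any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])) or bp[0] <= 0:
            raise ValueError("breakpoints must be positive and strictly increasing")

    @property
    def n_shells(self) -> int:
        return len(self.breakpoints) + 1

    def shell_indices(self, radii: np.ndarray | Sequence[float]) -> np.ndarray:
        """0-based shell index of each radius; half-open intervals [lo, hi)."""
        radii = np.asarray(radii, dtype=float)
        if np.any(radii < 0):
            raise ValueError("radii must be non-negative")
        return np.searchsorted(np.asarray(self.breakpoints), radii, side="right")


#: Ten shells: 0-10, 10-20, ..., 70-80, 80-100, beyond 100 (native length unit).
DEFAULT_LAYER_SCHEME = LayerScheme((10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 100.0))


@dataclass(frozen=True)
class LayerProfile:
    """Per-shell atom counts for one structure under one scheme."""

    counts: tuple[int, ...]
    scheme: LayerScheme

    def __post_init__(self) -> None:
        if len(self.counts) != self.scheme.n_shells:
            raise ValueError("count vector length must equal the scheme's shell count")
        if any(c < 0 for c in self.counts):
            raise ValueError("shell counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class ParameterSimilarityVector:
    """The nine per-parameter similarities for an ordered pair (query, target)."""

    s1: float  # shell density
    s2: float  # atom count
    s3: float  # residue count
    s4: float  # residue-type count
    s5: float  # C proportion
    s6: float  # N proportion
    s7: float  # O proportion
    s8: float  # P shell position
    s9: float  # S shell position

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.s1, self.s2, self.s3, self.s4, self.s5, self.s6, self.s7, self.s8, self.s9]
        )


@dataclass(frozen=True)
class WeightVector:
    """Linear-combination weights Q1..Q9 for the overall score."""

    q1: float
    q2: float
    q3: float
    q4: float
    q5: float
    q6: float
    q7: float
    q8: float
    q9: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.q1, self.q2, self.q3, self.q4, self.q5, self.q6, self.q7, self.q8, self.q9]
        )

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "WeightVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (9,):
            raise ValueError(f"expected 9 weights, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("weights must be finite")
        return cls(*(float(v) for v in arr))


def layer_profile(
    radii: np.ndarray | Sequence[float], scheme: LayerScheme = DEFAULT_LAYER_SCHEME
) -> LayerProfile:
    """Count atoms per shell.  Each radius lands in exactly one shell."""
    idx = scheme.shell_indices(radii)
    counts = np.bincount(idx, minlength=scheme.n_shells)
    return LayerProfile(counts=tuple(int(c) for c in counts), scheme=scheme)


def per_layer_similarity(p1: LayerProfile, p2: LayerProfile) -> np.ndarray:
    """Shell-wise similarity ``1 - |l1 - l2| / l1`` with p1 as the query.

    Shells empty in the query are undefined under the formula; they score 1
    when also empty in the target and 0 otherwise, which preserves the
    self-similarity identity.  Values can go below zero when the target
    shell holds more than twice the query's atoms.
    """
    if p1.scheme != p2.scheme:
        raise ValueError("profiles were built under different layer schemes")
    l1 = np.asarray(p1.counts, dtype=float)
    l2 = np.asarray(p2.counts, dtype=float)
    sim = np.empty_like(l1)
    nz = l1 > 0
    sim[nz] = 1.0 - np.abs(l1[nz] - l2[nz]) / l1[nz]
    sim[~nz] = np.where(l2[~nz] == 0, 1.0, 0.0)
    return sim


def layer_weights(p1: LayerProfile, p2: LayerProfile) -> np.ndarray:
    """Shell weights ``w_i = (l1_i/n1 + l2_i/n2) / 2``; they sum to one."""
    if p1.scheme != p2.scheme:
        raise ValueError("profiles were built under different layer schemes")
    if p1.total == 0 or p2.total == 0:
        raise ValueError("cannot weight empty profiles")
    f1 = np.asarray(p1.counts, dtype=float) / p1.total
    f2 = np.asarray(p2.counts, dtype=float) / p2.total
    return (f1 + f2) / 2.0


def density_similarity(
    s1: ProteinStructure,
    s2: ProteinStructure,
    scheme: LayerScheme = DEFAULT_LAYER_SCHEME,
) -> float:
    """Weighted sum of per-shell similarities; 1.0 for identical profiles."""
    p1 = layer_profile(radial_distances(s1), scheme)
    p2 = layer_profile(radial_distances(s2), scheme)
    return float(np.dot(layer_weights(p1, p2), per_layer_similarity(p1, p2)))


def scalar_similarity(n1: float, n2: float) -> float:
    """Relative-difference similarity ``1 - |n1 - n2| / n1`` (query first).

    Unclamped: the result is negative once the target exceeds twice the
    query value.  Invariant to scaling both arguments by the same positive
    factor.
    """
    if n1 <= 0:
        raise ValueError(f"query value must be positive, got {n1}")
    if n2 < 0:
        raise ValueError(f"target value must be non-negative, got {n2}")
    return 1.0 - abs(n1 - n2) / n1


def count_atoms(s: ProteinStructure) -> int:
    return len(s.atoms)


def count_residues(s: ProteinStructure) -> int:
    """Distinct (chain, residue_id) pairs."""
    return len({(a.chain, a.residue_id) for a in s.atoms})


def count_residue_types(s: ProteinStructure) -> int:
    """Distinct residue names among the 20 standard amino acids."""
    return len({a.residue_name for a in s.atoms if a.residue_name in STANDARD_AMINO_ACIDS})


def element_fraction(s: ProteinStructure, element: str) -> float:
    """Fraction of atoms with the given element symbol, in [0, 1]."""
    element = element.capitalize()
    matches = sum(1 for a in s.atoms if a.element.capitalize() == element)
    return matches / len(s.atoms)


def _element_shells(s: ProteinStructure, element: str, scheme: LayerScheme) -> np.ndarray:
    radii = radial_distances(s)
    idx = scheme.shell_indices(radii)
    mask = np.array([a.element.capitalize() == element for a in s.atoms])
    return np.unique(idx[mask])


def element_position_similarity(
    s1: ProteinStructure,
    s2: ProteinStructure,
    element: str,
    scheme: LayerScheme = DEFAULT_LAYER_SCHEME,
) -> float:
    """Positional similarity for a rare element (P or S).

    Same shell -> 1.0; adjacent shells -> 0.8; otherwise -> 0.0.  When either
    structure carries several such atoms, the best (maximum) cross-pair score
    is taken, which reduces to the plain rule in the single-atom case.
    Element absent from both structures counts as full similarity (1.0);
    absent from exactly one scores 0.0.
    """
    element = element.capitalize()
    if element not in ("P", "S"):
        raise ValueError(f"positional similarity is defined for P and S, got {element!r}")
    shells1 = _element_shells(s1, element, scheme)
    shells2 = _element_shells(s2, element, scheme)
    if len(shells1) == 0 and len(shells2) == 0:
        return 1.0
    if len(shells1) == 0 or len(shells2) == 0:
        return 0.0
    diff = np.abs(shells1[:, None] - shells2[None, :]).min()
    if diff == 0:
        return 1.0
    if diff == 1:
        return 0.8
    return 0.0


def parameter_vector(
    s1: ProteinStructure,
    s2: ProteinStructure,
    scheme: LayerScheme = DEFAULT_LAYER_SCHEME,
) -> ParameterSimilarityVector:
    """Assemble S1..S9 for the ordered pair (query s1, target s2)."""
    return ParameterSimilarityVector(
        s1=density_similarity(s1, s2, scheme),
        s2=scalar_similarity(count_atoms(s1), count_atoms(s2)),
        s3=scalar_similarity(count_residues(s1), count_residues(s2)),
        s4=scalar_similarity(count_residue_types(s1), count_residue_types(s2)),
        s5=scalar_similarity(element_fraction(s1, "C"), element_fraction(s2, "C")),
        s6=scalar_similarity(element_fraction(s1, "N"), element_fraction(s2, "N")),
        s7=scalar_similarity(element_fraction(s1, "O"), element_fraction(s2, "O")),
        s8=element_position_similarity(s1, s2, "P", scheme),
        s9=element_position_similarity(s1, s2, "S", scheme),
    )


def overall_similarity(v: ParameterSimilarityVector, w: WeightVector) -> float:
    """Plain dot product of similarities and weights; no clamping."""
    return float(np.dot(v.as_array(), w.as_array()))


def rank_reference_proteins(
    rows: Iterable[tuple[str, ParameterSimilarityVector]], w: WeightVector
) -> list[tuple[str, float]]:
    """Score named parameter vectors and sort descending (ties by name)."""
    scored = [(name, overall_similarity(v, w)) for name, v in rows]
    if not scored:
        raise ValueError("no rows to rank")
    return sorted(scored, key=lambda t: (-t[1], t[0]))
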