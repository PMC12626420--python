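"""Microexon sequence utilities: definition filter, conservation, splicing
layout classification, and RT-PCR / qRT-PCR quantification.

Microexons are alternatively spliced exons of 3-30 nucleotides (1-10 amino
acids), typically frame-preserving and neuronally included.  Their Srrm4-
dependent regulation is marked by intronic features directly upstream of the
exon: UGC repeats and a UC-repeat-like polypyrimidine tract.  This module
provides:

* the length-definition filter,
* pairwise peptide percent identity (global alignment, identity scoring)
  and the microexon/full-protein conservation ratio,
* a rule-based upstream-layout classifier (canonical / partial /
  noncanonical),
* exon inclusion fractions from gel band intensities
  (included / (included + skipped)),
* average-linkage clustering of developmental inclusion profiles with a
  Newick export of the dendrogram,
* relative expression by the 2^-ddCt method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "MicroexonRecord",
    "InclusionProfile",
    "microexon_length_filter",
    "percent_identity",
    "identity_ratio",
    "classify_upstream_layout",
    "rtpcr_inclusion",
    "cluster_inclusion_profiles",
    "linkage_to_newick",
    "ddct",
    "MIN_NT",
    "MAX_NT",
]

MIN_NT, MAX_NT = 3, 30

_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
_NUCLEOTIDE_ALPHABET = set("ACGTU")


@dataclass(frozen=True)
class MicroexonRecord:
    """One microexon with its ortholog context.

    ``upstream_intron`` is given 5'->3' and ends at the exon boundary.
    ``layout_class`` is the generator's ground-truth label when the record
    is synthetic; None for real data.
    """

    gene: str
    nt_seq: str
    peptide: str
    ortholog_peptide: str
    full_protein_identity: float
    upstream_intron: str
    frame_preserving: bool = True
    layout_class: str | None = None

    def __post_init__(self) -> None:
        if self.frame_preserving and self.peptide:
            if len(self.nt_seq) != 3 * len(self.peptide):
                raise ValueError(
                    f"{self.gene}: frame-preserving record needs nt length == 3 x aa length"
                )


@dataclass(frozen=True)
class InclusionProfile:
    """Per-stage inclusion fraction of one microexon across development."""

    microexon_id: str
    stages: tuple[str, ...]
    inclusion: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.stages) != len(self.inclusion):
            raise ValueError("stages and inclusion must align")
        if any(not 0.0 <= f <= 1.0 for f in self.inclusion):
            raise ValueError("inclusion fractions must be in [0, 1]")


# ---------------------------------------------------------------------------
# definition filter and conservation
# ---------------------------------------------------------------------------

def microexon_length_filter(record: MicroexonRecord | str) -> bool:
    """True iff the exon is 3-30 nt (1-10 aa for frame-preserving exons)."""
    nt = record if isinstance(record, str) else record.nt_seq
    if len(nt) == 0:
        raise ValueError("empty exon sequence")
    return MIN_NT <= len(nt) <= MAX_NT


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def percent_identity(
    pep_a: str,
    pep_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> float:
    """Percent identity from a global alignment with linear gap penalty.

    Identity = matched columns / total alignment columns x 100, taken from a
    highest-scoring alignment.  Symmetric in its arguments.
    """
    for pep in (pep_a, pep_b):
        if not pep:
            raise ValueError("empty peptide")
        bad = set(pep.upper()) - _PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"invalid residue characters {sorted(bad)!r}")
    a, b = pep_a.upper(), pep_b.upper()
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(c1 == c2 and c1 != "-" for c1, c2 in zip(s1, s2))
    return 100.0 * matches / len(s1)


def identity_ratio(microexon_identity: float, full_protein_identity: float) -> float:
    """Microexon identity divided by full-protein identity (> 1 means the
    microexon is more conserved than its protein)."""
    if full_protein_identity == 0:
        return float("nan")
    return microexon_identity / full_protein_identity


# ---------------------------------------------------------------------------
# upstream regulatory layout
# ---------------------------------------------------------------------------

def _has_ugc_repeat(proximal: str, min_ugc: int) -> bool:
    count = start = 0
    while True:
        hit = proximal.find("UGC", start)
        if hit < 0:
            break
        count += 1
        start = hit + 1
    return count >= min_ugc


def _has_pyrimidine_tract(window: str, min_len: int, min_frac: float) -> bool:
    if len(window) < min_len:
        return False
    is_pyr = np.frombuffer(window.encode(), dtype=np.uint8)
    is_pyr = np.isin(is_pyr, np.frombuffer(b"CU", dtype=np.uint8)).astype(int)
    kernel = np.convolve(is_pyr, np.ones(min_len, dtype=int), mode="valid")
    return bool((kernel >= min_frac * min_len - 1e-9).any())


def classify_upstream_layout(
    intron_seq: str,
    window: int = 100,
    proximal: int = 30,
    min_ugc: int = 2,
    tract_min_len: int = 10,
    tract_min_frac: float = 0.75,
) -> str:
    """Classify the intronic layout directly upstream of a microexon.

    Two features are scanned in the window upstream of the 3' end (the exon
    boundary): a UGC repeat (>= ``min_ugc`` UGC occurrences within the
    proximal ``proximal`` nt) and a polypyrimidine tract (a run of
    ``tract_min_len`` nt with pyrimidine fraction >= ``tract_min_frac``
    anywhere in the window).  Both features -> ``canonical``; exactly one ->
    ``partial``; neither -> ``noncanonical``.  DNA input is transcribed
    (T -> U) before scanning.
    """
    seq = intron_seq.upper().replace("T", "U")
    bad = set(seq) - _NUCLEOTIDE_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide characters {sorted(bad)!r}")
    win = seq[-window:] if len(seq) >= window else seq
    prox = win[-proximal:]
    ugc = _has_ugc_repeat(prox, min_ugc)
    tract = _has_pyrimidine_tract(win, tract_min_len, tract_min_frac)
    if ugc and tract:
        return "canonical"
    if ugc or tract:
        return "partial"
    return "noncanonical"


# ---------------------------------------------------------------------------
# RT-PCR / qRT-PCR quantification
# ---------------------------------------------------------------------------

def rtpcr_inclusion(included_intensity: float, skipped_intensity: float) -> float:
    """Exon inclusion fraction from gel band intensities.

    included / (included + skipped); NaN when both bands are absent.
    """
    if included_intensity < 0 or skipped_intensity < 0:
        raise ValueError("band intensities must be nonnegative")
    total = included_intensity + skipped_intensity
    if total == 0:
        return float("nan")
    return included_intensity / total


def cluster_inclusion_profiles(
    profiles: pd.DataFrame,
) -> tuple[list[str], np.ndarray]:
    """Hierarchically cluster inclusion profiles (rows = microexons).

    Average linkage on Euclidean distances (the clustered-heatmap default);
    returns the leaf ordering of row labels and the scipy linkage matrix.
    """
    if profiles.isna().any().any():
        raise ValueError("profiles contain missing values; impute before clustering")
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    lm = linkage(pdist(profiles.to_numpy(dtype=float)), method="average")
    order = [profiles.index[i] for i in leaves_list(lm)]
    return order, lm


def linkage_to_newick(lm: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: str(labels[i]) for i in range(n)}
    for k, (i, j, h, _) in enumerate(lm):
        i, j = int(i), int(j)
        bi = h - heights[i]
        bj = h - heights[j]
        nodes[n + k] = f"({nodes[i]}:{bi:g},{nodes[j]}:{bj:g})"
        heights[n + k] = h
    return nodes[n + len(lm) - 1] + ";"


def ddct(
    ct_target: np.ndarray | Sequence[float],
    ct_reference: np.ndarray | Sequence[float],
    control_group: np.ndarray | Sequence[bool],
) -> np.ndarray:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) per sample; ddCt is relative to the
    mean dCt of the control group, whose mean relative expression is 1 by
    construction.
    """
    ct_t = np.asarray(ct_target, dtype=float)
    ct_r = np.asarray(ct_reference, dtype=float)
    ctrl = np.asarray(control_group, dtype=bool)
    if not (ct_t.shape == ct_r.shape == ctrl.shape):
        raise ValueError("ct_target, ct_reference and control_group must align")
    if not np.isfinite(ct_t).all() or not np.isfinite(ct_r).all():
        raise ValueError("Ct values must be finite")
    if not ctrl.any():
        raise ValueError("control group is empty")
    dct = ct_t - ct_r
    dd = dct - dct[ctrl].mean()
    return 2.0 ** (-dd)
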