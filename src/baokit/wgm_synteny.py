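"""Synonymous distances, Ks peaks, WGM dating, and synteny-block chaining.

Whole-genome multiplications (WGMs) leave two signatures: a burst of paralog
pairs at a common synonymous distance Ks, and multiple collinear copies of
each chromosomal region. This module computes Nei-Gojobori (1986) Ks for
codon-aligned pairs, finds Ks peaks by kernel density, converts Ks to time
via T = Ks / (2 r) with a default substitution rate of 6.56e-9 per synonymous
site per year, chains anchor pairs into collinear blocks, and summarizes
syntenic depth and post-WGM gene copy retention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .io import warn

DEFAULT_KS_RATE = 6.56e-9

_BASES = "ACGT"
_CODON_TABLE = {}
_STOPS = {"TAA", "TAG", "TGA"}


def _build_codon_table():
    from Bio.Data.CodonTable import standard_dna_table

    _CODON_TABLE.update(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        _CODON_TABLE[stop] = "*"


_build_codon_table()


# ------------------------------------------------------------------ NG86 core

def _synonymous_sites(codon: str) -> float:
    """Synonymous site count of one codon (NG86).

    Each position contributes the fraction of its single-nucleotide changes
    that are synonymous; changes creating stop codons are excluded from the
    site counts.
    """
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        possible = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            possible += 1
            if _CODON_TABLE[alt] == aa:
                syn += 1
        if possible:
            s += syn / possible
    return s


_SYN_SITES_CACHE = {c: _synonymous_sites(c) for c in map("".join, itertools.product(_BASES, repeat=3))
                    if c not in _STOPS}


def _pathway_differences(codon_a: str, codon_b: str):
    """Average synonymous/nonsynonymous difference counts over mutational
    pathways between two codons (equal path weighting; paths through stop
    codons excluded unless all paths hit a stop)."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:  # all pathways pass through a stop: fall back to all paths
        for order in itertools.permutations(diff_pos):
            cur = codon_a
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                if _CODON_TABLE[cur] == _CODON_TABLE[nxt] and nxt not in _STOPS:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            results.append((sd, nd))
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd


@dataclass
class KsRecord:
    """Per-pair synonymous distance (NG86 with Jukes-Cantor correction)."""

    s_sites: float
    sd: float
    ps: float
    ks: float
    saturated: bool = False
    gene_a: str = ""
    gene_b: str = ""


def compute_ks(cds_a: str, cds_b: str, gene_a: str = "", gene_b: str = "") -> KsRecord:
    """Nei-Gojobori 1986 synonymous distance for a codon-aligned CDS pair.

    Sequences must be equal length, a multiple of 3, without internal stops
    (gap columns removed beforehand). Synonymous sites S are averaged over
    the two sequences; pS = Sd/S; Ks applies the Jukes-Cantor correction
    ``Ks = -3/4 ln(1 - 4 pS / 3)``, flagged saturated (infinite) at
    pS >= 0.75.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be equal length (codon-aligned)")
    if len(a) % 3:
        raise ValueError("length must be divisible by 3")
    codons_a = [a[i : i + 3] for i in range(0, len(a), 3)]
    codons_b = [b[i : i + 3] for i in range(0, len(b), 3)]
    for name, codons in (("first", codons_a), ("second", codons_b)):
        internal = codons[:-1]
        if any(c in _STOPS for c in internal):
            raise ValueError(f"internal stop codon in {name} sequence")
    if codons_a[-1] in _STOPS and codons_b[-1] in _STOPS:
        codons_a, codons_b = codons_a[:-1], codons_b[:-1]
    s_a = sum(_SYN_SITES_CACHE[c] for c in codons_a)
    s_b = sum(_SYN_SITES_CACHE[c] for c in codons_b)
    s_sites = (s_a + s_b) / 2.0
    sd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        d, _ = _pathway_differences(ca, cb)
        sd += d
    ps = sd / s_sites if s_sites > 0 else 0.0
    if ps >= 0.75:
        return KsRecord(s_sites, sd, ps, np.inf, saturated=True, gene_a=gene_a, gene_b=gene_b)
    ks = -0.75 * np.log(1.0 - 4.0 * ps / 3.0)
    return KsRecord(s_sites, sd, ps, float(ks), gene_a=gene_a, gene_b=gene_b)


# ------------------------------------------------------------------- Ks peaks

def ks_peaks(ks_values, bandwidth: float | None = None, ks_range=(0.0, 3.0)):
    """Detect Ks distribution peaks by Gaussian kernel density.

    Peaks are local density maxima with height >= 10% of the global maximum,
    inside ``ks_range``, sorted ascending. Returns a list of
    ``(ks_mode, weight)`` with weight the relative density height.
    """
    vals = np.asarray([k for k in ks_values if np.isfinite(k)], dtype=float)
    vals = vals[(vals > ks_range[0]) & (vals <= ks_range[1])]
    if vals.size == 0:
        raise ValueError("no finite Ks values in range (all saturated or empty)")
    if vals.size < 50:
        warn(f"only {vals.size} finite Ks values; >= 50 recommended")
    if np.ptp(vals) == 0:
        return [(float(vals[0]), 1.0)]
    kde = gaussian_kde(vals, bw_method=bandwidth)
    grid = np.linspace(ks_range[0], ks_range[1], 1024)
    dens = kde(grid)
    peaks, props = find_peaks(dens, height=0.1 * dens.max())
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
        props = {"peak_heights": np.array([dens.max()])}
    gmax = dens.max()
    out = [(float(grid[p]), float(h / gmax)) for p, h in zip(peaks, props["peak_heights"])]
    return sorted(out)


def ks_to_time(ks: float, rate: float = DEFAULT_KS_RATE) -> float:
    """Convert a synonymous distance to years: T = Ks / (2 r)."""
    if ks < 0 or rate <= 0:
        raise ValueError("ks must be >= 0 and rate > 0")
    return ks / (2.0 * rate)


# ------------------------------------------------------------------- chaining

@dataclass
class SyntenyBlock:
    query_chrom: str
    target_chrom: str
    orientation: int  # +1 or -1
    anchor_indices: list  # row indices into the anchor table
    query_span: tuple
    target_span: tuple

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_indices)


@dataclass
class SyntenyBlocks:
    blocks: list
    anchors: pd.DataFrame
    unplaced: int = 0


def _best_chain_dp(qpos, tpos, max_gap):
    """Best collinear chain (max anchors) among anchors sorted by (q, t).

    Tries both orientations; among maximal chains the one with the
    lexicographically smallest sequence of (query, target) ordinals wins
    (forward orientation preferred on residual ties). A chain must be
    strictly increasing in query ordinal and strictly monotone in target
    ordinal, with consecutive ordinal differences <= max_gap in both genomes.
    Returns a list of positions into the sorted arrays.
    """
    n = qpos.size
    best = []
    best_key = None
    for orient in (1, -1):
        t = tpos * orient
        # g[i]: longest valid chain starting at anchor i
        g = np.ones(n, dtype=int)
        for i in range(n - 2, -1, -1):
            for j in range(i + 1, n):
                if qpos[j] - qpos[i] > max_gap:
                    break
                if (qpos[j] > qpos[i] and t[j] > t[i]
                        and abs(tpos[j] - tpos[i]) <= max_gap and g[j] + 1 > g[i]):
                    g[i] = g[j] + 1
        best_len = int(g.max())
        # greedy reconstruction of the lexicographically smallest maximal chain
        start = int(np.flatnonzero(g == best_len)[0])
        chain = [start]
        need = best_len - 1
        cur = start
        while need:
            for j in range(cur + 1, n):
                if qpos[j] - qpos[cur] > max_gap:
                    break
                if (qpos[j] > qpos[cur] and t[j] > t[cur]
                        and abs(tpos[j] - tpos[cur]) <= max_gap and g[j] == need):
                    chain.append(j)
                    cur = j
                    need -= 1
                    break
            else:
                break
        key = [(int(qpos[i]), int(tpos[i])) for i in chain]
        if len(chain) > len(best) or (len(chain) == len(best) and best and key < best_key):
            best, best_key = chain, key
    return best


def chain_anchors(anchors: pd.DataFrame, min_anchors: int = 4, max_gap_genes: int = 20) -> SyntenyBlocks:
    """Chain collinear anchors into synteny blocks per chromosome pair.

    Dynamic-programming chaining with chain score = anchor count, both
    orientations tried; consecutive anchors must be within ``max_gap_genes``
    ordinal positions in both genomes. Blocks are extracted best-first (ties
    to the chain with the earliest query ordinals), each anchor assigned to
    at most one block; chains shorter than ``min_anchors`` are discarded.
    """
    df = anchors.copy()
    dup = df.duplicated(subset=["chromA", "posA", "chromB", "posB"])
    if dup.any():
        warn(f"collapsed {int(dup.sum())} duplicate anchors")
        df = df[~dup]
    df = df.reset_index(drop=True)
    blocks = []
    placed = np.zeros(len(df), dtype=bool)
    for (qc, tc), sub in df.groupby(["chromA", "chromB"], sort=True):
        avail = sub.index.to_numpy()
        while True:
            live = avail[~placed[avail]]
            if live.size < min_anchors:
                break
            qa = df.loc[live, "posA"].to_numpy()
            tb = df.loc[live, "posB"].to_numpy()
            order = np.lexsort((tb, qa))
            live = live[order]
            qpos = qa[order]
            tpos = tb[order]
            chain = _best_chain_dp(qpos, tpos, max_gap_genes)
            if len(chain) < min_anchors:
                break
            rows = live[chain]
            placed[rows] = True
            tvals = df.loc[rows, "posB"].to_numpy()
            orient = 1 if tvals[-1] >= tvals[0] else -1
            blocks.append(
                SyntenyBlock(
                    query_chrom=qc,
                    target_chrom=tc,
                    orientation=orient,
                    anchor_indices=list(rows),
                    query_span=(int(df.loc[rows, "posA"].min()), int(df.loc[rows, "posA"].max())),
                    target_span=(int(tvals.min()), int(tvals.max())),
                )
            )
    # deterministic block order: by size desc, then query chrom/span
    blocks.sort(key=lambda b: (-b.n_anchors, b.query_chrom, b.query_span, b.target_chrom))
    return SyntenyBlocks(blocks=blocks, anchors=df, unplaced=int((~placed).sum()))


def depth_and_retention(blocks: SyntenyBlocks, query_gene_count: int):
    """Syntenic depth per query gene and the copy-retention profile.

    Depth of a gene is the number of blocks whose query-ordinal span covers
    it. Returns ``(headline_ratio, profile)`` where the headline ratio is the
    modal nonzero depth as a string "d:1" and the profile maps depth 0..5 to
    the fraction of query genes at that depth (depths above 5 are pooled
    under ``">5"``).
    """
    depth = np.zeros(query_gene_count, dtype=int)
    for b in blocks.blocks:
        lo, hi = b.query_span
        lo = max(lo, 0)
        hi = min(hi, query_gene_count - 1)
        if hi >= lo:
            depth[lo : hi + 1] += 1
    profile = {d: float(np.mean(depth == d)) for d in range(6)}
    profile[">5"] = float(np.mean(depth > 5))
    nonzero = depth[depth > 0]
    if nonzero.size:
        counts = np.bincount(nonzero)
        modal = int(np.argmax(counts))
        ratio = f"{modal}:1"
    else:
        ratio = "0:1"
    return ratio, profile
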