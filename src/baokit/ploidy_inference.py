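"""Ploidy inference from allele balance at heterozygous biallelic sites.

At a heterozygous site of a sequenced individual, the fraction of reads
carrying the alternate allele concentrates near dosage/ploidy: a diploid
shows a single (folded) peak at 1/2, an autotetraploid two folded peaks near
1/4 and 1/2. Model selection follows the nQuire convention: for each ploidy
hypothesis P a Gaussian mixture with fixed means {i/P} (free weights, shared
variance) is fit by EM on the unfolded fractions and compared against a free
3-component mixture; the hypothesis with the smallest log-likelihood gap to
the free model wins, with a small per-component parsimony penalty so that
nested hypotheses (a tetraploid mixture can imitate a diploid by zeroing two
weights) do not beat simpler ones on noise alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.special import logsumexp

from ._util import moving_average3
from .io import warn

ALLELE_TABLE_COLUMNS = ["chrom", "pos", "ref_depth", "alt_depth", "qual"]


@dataclass
class PloidyCall:
    """Result of fixed-mean mixture model selection over ploidy hypotheses."""

    called_ploidy: int
    loglik_fixed: dict
    loglik_free: float
    delta_loglik: dict
    detected_modes: list
    histogram: tuple
    converged: bool = True
    n_sites: int = 0
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "called_ploidy": self.called_ploidy,
            "loglik_fixed": {str(k): v for k, v in self.loglik_fixed.items()},
            "loglik_free": self.loglik_free,
            "delta_loglik": {str(k): v for k, v in self.delta_loglik.items()},
            "detected_modes": list(map(float, self.detected_modes)),
            "converged": self.converged,
            "n_sites": self.n_sites,
            "notes": self.notes,
        }


# ------------------------------------------------------------------ VCF input

def extract_allele_balance(vcf_path, sample: str | None = None, min_qual: float = 20.0,
                           min_depth: int = 20, max_depth: float | None = None) -> pd.DataFrame:
    """Extract per-site allele depths for one sample from a VCF.

    Retains heterozygous biallelic SNPs with quality >= ``min_qual`` and total
    allele depth inside [``min_depth``, ``max_depth``]; ``max_depth`` defaults
    to 3x the median depth of retained candidates (collapsed-repeat guard).
    Requires the per-sample AD FORMAT field.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    if not samples:
        raise ValueError("VCF has no samples")
    if sample is None:
        s_idx = 0
    else:
        if sample not in samples:
            raise ValueError(f"sample {sample!r} not in VCF (has {samples})")
        s_idx = samples.index(sample)
    rows = []
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            continue
        if variant.QUAL is None or variant.QUAL < min_qual:
            continue
        try:
            ad = variant.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError("VCF is missing the per-sample AD (allelic depth) FORMAT field")
        ref_d, alt_d = int(ad[s_idx][0]), int(ad[s_idx][1])
        if ref_d < 1 or alt_d < 1:
            continue  # not heterozygous evidence
        rows.append((variant.CHROM, variant.POS, ref_d, alt_d, float(variant.QUAL)))
    if not rows:
        raise ValueError("no heterozygous biallelic sites passed the filters")
    table = pd.DataFrame(rows, columns=ALLELE_TABLE_COLUMNS)
    total = table["ref_depth"] + table["alt_depth"]
    if max_depth is None:
        max_depth = 3.0 * float(np.median(total))
    table = table[(total >= min_depth) & (total <= max_depth)].reset_index(drop=True)
    if table.empty:
        raise ValueError("no sites left inside the depth window")
    return table


def allele_fractions(table: pd.DataFrame, fold: bool = False) -> np.ndarray:
    """Alternate-allele read fractions; folded to minor fractions if asked.

    Folding is computed as min(ref, alt)/total so it is exactly invariant
    under swapping the two depth columns.
    """
    ref = table["ref_depth"].to_numpy(float)
    alt = table["alt_depth"].to_numpy(float)
    total = ref + alt
    if fold:
        return np.minimum(ref, alt) / total
    return alt / total


# ------------------------------------------------------------------ histogram

def histogram_modes(table: pd.DataFrame, bin_width: float = 0.02, fold: bool = True):
    """Detect modes of the (folded) allele-fraction histogram.

    Bins the fractions at ``bin_width``, smooths with a 3-bin moving average,
    and reports local maxima with prominence >= 10% of the tallest bin,
    merging modes closer than 0.05 (the taller one wins). Returns
    ``(modes, (bin_centers, counts))`` with modes ascending.
    """
    if not 0 < bin_width <= 0.25:
        raise ValueError("bin_width must lie in (0, 0.25]")
    if len(table) < 1000:
        warn(f"only {len(table)} sites; at least 1000 recommended for stable modes")
    frac = allele_fractions(table, fold=fold)
    upper = 0.5 if fold else 1.0
    edges = np.arange(0.0, upper + bin_width / 2, bin_width)
    if edges[-1] < upper:
        edges = np.append(edges, upper)
    counts, _ = np.histogram(frac, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    smoothed = moving_average3(counts.astype(float))
    if smoothed.max() <= 0:
        return [], (centers, counts)
    padded = np.concatenate([[-1.0], smoothed, [-1.0]])
    peaks, props = find_peaks(padded, prominence=0.1 * smoothed.max())
    peaks = peaks - 1
    order = np.argsort(-smoothed[peaks])
    kept: list[int] = []
    for p in peaks[order]:
        if all(abs(centers[p] - centers[q]) >= 0.05 for q in kept):
            kept.append(p)
    modes = sorted(float(centers[p]) for p in kept)
    return modes, (centers, counts)


def coverage_fraction_hist2d(table: pd.DataFrame, depth_bins=None, fraction_bins=None):
    """2-D histogram of total depth x folded minor-allele fraction.

    The marginal over depth equals the 1-D folded histogram on the same
    fraction bins. Returns ``(H, depth_edges, fraction_edges)``.
    """
    if table.empty:
        raise ValueError("empty allele-depth table")
    total = (table["ref_depth"] + table["alt_depth"]).to_numpy(float)
    frac = allele_fractions(table, fold=True)
    if depth_bins is None:
        depth_bins = np.linspace(total.min(), total.max() + 1, 21)
    if fraction_bins is None:
        fraction_bins = np.arange(0.0, 0.52, 0.02)
    depth_bins = np.asarray(depth_bins, float)
    fraction_bins = np.asarray(fraction_bins, float)
    if depth_bins.size < 2 or fraction_bins.size < 2:
        raise ValueError("bin edge arrays must define at least one bin")
    H, de, fe = np.histogram2d(total, frac, bins=[depth_bins, fraction_bins])
    return H, de, fe


# ------------------------------------------------------------------------- EM

def _em_gaussian_mixture(x: np.ndarray, means: np.ndarray, free_means: bool,
                         max_iter: int = 200, tol: float = 1e-6,
                         var_floor: float = 1e-4):
    """EM for a shared-variance Gaussian mixture; means optionally free.

    Weights start uniform; the shared variance is floored at ``var_floor``.
    Returns (loglik, weights, means, variance, converged).
    """
    n, m = x.size, means.size
    mu = means.astype(float).copy()
    w = np.full(m, 1.0 / m)
    var = max(float(np.var(x)), var_floor)
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        log_comp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2 * np.pi * var)
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var
        )
        log_norm = logsumexp(log_comp, axis=1)
        loglik = float(log_norm.sum())
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0)
        w = np.maximum(nk, 1e-12) / n
        w /= w.sum()
        if free_means:
            mu = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
        var = max(float((resp * (x[:, None] - mu[None, :]) ** 2).sum() / n), var_floor)
        if abs(loglik - prev) < tol:
            converged = True
            break
        prev = loglik
    return loglik, w, mu, var, converged


def classify_ploidy(table: pd.DataFrame, hypotheses=(2, 3, 4),
                    parsimony_penalty: float = 3.0) -> PloidyCall:
    """Call ploidy by fixed-mean mixture model selection on unfolded fractions.

    For each hypothesis P the fixed model has means {i/P : i=1..P-1}; the
    reference free model has 3 components with free means. The call minimizes
    ``delta = loglik_free - loglik_fixed`` plus ``parsimony_penalty`` per
    component beyond the diploid model's single one, with exact ties broken
    toward the smaller ploidy.
    """
    x = allele_fractions(table, fold=False)
    x = x[(x > 0) & (x < 1)]
    if x.size == 0:
        raise ValueError("no usable allele fractions in (0, 1)")
    q = np.quantile(x, [0.25, 0.5, 0.75])
    ll_free, _, _, _, conv_free = _em_gaussian_mixture(x, q, free_means=True)
    loglik_fixed, delta, converged = {}, {}, conv_free
    for P in sorted(hypotheses):
        means = np.arange(1, P) / P
        ll, _, _, _, conv = _em_gaussian_mixture(x, means, free_means=False)
        loglik_fixed[P] = ll
        delta[P] = ll_free - ll
        converged = converged and conv
    scores = {P: delta[P] + parsimony_penalty * (P - 2) for P in delta}
    called = min(sorted(scores), key=lambda P: (scores[P], P))
    modes, hist = histogram_modes(table, fold=True)
    notes = [] if converged else ["unconverged"]
    return PloidyCall(
        called_ploidy=called,
        loglik_fixed=loglik_fixed,
        loglik_free=ll_free,
        delta_loglik=delta,
        detected_modes=modes,
        histogram=hist,
        converged=converged,
        n_sites=int(x.size),
        notes=notes,
    )
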