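"""Population differentiation and structure from genotype dosages.

Implements the Weir & Cockerham (1984) Fst estimator from per-locus variance
components (a: among populations, b: among individuals within populations,
c: within individuals), with the weighted multi-locus estimate
``sum(a) / sum(a+b+c)``; a frequency-based Hudson estimator is provided as a
ploidy-agnostic alternative. Tetraploid dosages are "diploidized" (0..4
mapped to 0/1/2) for the WC84 path, since the estimator's heterozygosity
terms assume a diploid genotype model. Genotype PCA and a lostruct-style
windowed local PCA with classical MDS over window distances complete the
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import warn


@dataclass
class GenotypeMatrix:
    """Samples x loci alternate-allele dosages with population labels.

    ``dosages`` is an integer matrix (missing = -1); ``ploidy`` is per-sample
    (2 or 4); ``chrom``/``pos`` give locus coordinates (1-based).
    """

    dosages: np.ndarray
    samples: list
    ploidy: np.ndarray
    populations: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        self.ploidy = np.asarray(self.ploidy)
        self.populations = np.asarray(self.populations)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos)
        n, m = self.dosages.shape
        if len(self.samples) != n or self.ploidy.size != n or self.populations.size != n:
            raise ValueError("sample metadata length mismatch")
        if self.chrom.size != m or self.pos.size != m:
            raise ValueError("locus metadata length mismatch")
        valid = self.dosages >= 0
        if np.any(self.dosages[valid] > self.ploidy[:, None].repeat(m, 1)[valid]):
            raise ValueError("dosage exceeds sample ploidy")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def diploidized(self) -> np.ndarray:
        """Dosages mapped to 0/1/2 (tetraploid d -> floor(d/2 + 1/2))."""
        d = self.dosages.astype(float)
        out = d.copy()
        tetra = self.ploidy == 4
        out[tetra] = np.floor(d[tetra] / 2 + 0.5)
        out[d < 0] = -1
        return out.astype(int)

    @classmethod
    def from_vcf(cls, path, pop_map: dict) -> "GenotypeMatrix":
        """Load GT dosages from a VCF (ploidy 2 or 4 calls)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = vcf.samples
        rows_chrom, rows_pos, cols = [], [], []
        ploidy = None
        for v in vcf:
            if len(v.ALT) != 1:
                continue
            gt = v.genotype.array()
            alleles = gt[:, :-1]  # last column is phasing flag
            if ploidy is None:
                ploidy = np.array([(row >= 0).sum() for row in alleles])
            dos = np.where((alleles >= 0).any(axis=1), (alleles > 0).sum(axis=1), -1)
            rows_chrom.append(v.CHROM)
            rows_pos.append(v.POS)
            cols.append(dos)
        if not cols:
            raise ValueError("no biallelic sites in VCF")
        return cls(
            dosages=np.stack(cols, axis=1),
            samples=samples,
            ploidy=ploidy,
            populations=np.array([pop_map.get(s, "unknown") for s in samples]),
            chrom=np.array(rows_chrom),
            pos=np.array(rows_pos),
        )


@dataclass
class FstResult:
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    per_locus_fst: np.ndarray
    weighted_fst: float
    pops: tuple
    n_excluded: int
    chrom: np.ndarray = None
    pos: np.ndarray = None
    undefined: bool = False


def wc84_components(counts_het: np.ndarray, freqs: np.ndarray, sizes: np.ndarray):
    """Weir-Cockerham 1984 per-locus variance components for r populations.

    Parameters are per-population arrays over loci: ``freqs[i, l]`` the
    alternate-allele frequency, ``counts_het[i, l]`` the observed
    heterozygote *frequency*, ``sizes[i, l]`` the number of individuals.
    Returns (a, b, c) arrays over loci.
    """
    r = freqs.shape[0]
    n_i = sizes.astype(float)
    nbar = n_i.mean(axis=0)
    nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n_i * freqs).sum(axis=0) / (r * nbar)
    s2 = (n_i * (freqs - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * counts_het).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def weighted_fst(geno: GenotypeMatrix, pop_a: str, pop_b: str,
                 mode: str = "wc84") -> FstResult:
    """Weighted Fst between two populations.

    ``mode='wc84'`` uses Weir-Cockerham variance components on diploidized
    genotype calls (observed heterozygosity from the calls);
    ``mode='hudson'`` uses the frequency-based Hudson estimator, which needs
    no heterozygosity and is ploidy-agnostic. Monomorphic loci (undefined
    components) are excluded and counted.
    """
    for pop in (pop_a, pop_b):
        if (geno.populations == pop).sum() < 2:
            raise ValueError(f"population {pop!r} needs at least 2 samples")
    sel = [np.flatnonzero(geno.populations == p) for p in (pop_a, pop_b)]
    if mode == "wc84":
        dip = geno.diploidized().astype(float)
        dip[dip < 0] = np.nan
        freqs, hets, sizes = [], [], []
        for rows in sel:
            sub = dip[rows]
            n = np.sum(~np.isnan(sub), axis=0).astype(float)
            freqs.append(np.nansum(sub, axis=0) / (2 * np.maximum(n, 1)))
            hets.append(np.nanmean(sub == 1, axis=0))
            sizes.append(n)
        a, b, c = wc84_components(np.array(hets), np.array(freqs), np.array(sizes))
        denom = a + b + c
        ok = np.isfinite(denom) & (denom > 0)
        per_locus = np.full(a.size, np.nan)
        per_locus[ok] = a[ok] / denom[ok]
        tot = float(denom[ok].sum())
        weighted = float(a[ok].sum() / tot) if ok.any() and tot > 0 else np.nan
        return FstResult(
            a=a, b=b, c=c, per_locus_fst=per_locus, weighted_fst=weighted,
            pops=(pop_a, pop_b), n_excluded=int((~ok).sum()),
            chrom=geno.chrom, pos=geno.pos, undefined=not ok.any(),
        )
    if mode == "hudson":
        dos = geno.dosages.astype(float)
        dos[dos < 0] = np.nan
        num_l, den_l = [], []
        for rows in sel:
            sub = dos[rows]
            pl = geno.ploidy[rows][:, None]
            n_al = np.sum(~np.isnan(sub) * pl, axis=0).astype(float)
            p = np.nansum(sub, axis=0) / np.maximum(n_al, 1)
            num_l.append((p, n_al))
        (p1, n1), (p2, n2) = num_l
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / np.maximum(n1 - 1, 1) - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        ok = den > 0
        per_locus = np.full(num.size, np.nan)
        per_locus[ok] = num[ok] / den[ok]
        weighted = float(num[ok].sum() / den[ok].sum()) if ok.any() else np.nan
        z = np.zeros(num.size)
        return FstResult(
            a=num, b=z, c=den - num, per_locus_fst=per_locus, weighted_fst=weighted,
            pops=(pop_a, pop_b), n_excluded=int((~ok).sum()),
            chrom=geno.chrom, pos=geno.pos, undefined=not ok.any(),
        )
    raise ValueError("mode must be 'wc84' or 'hudson'")


def high_fst_loci(result: FstResult, threshold: float = 0.8) -> pd.DataFrame:
    """Loci with per-locus Fst above ``threshold``, with coordinates."""
    sel = np.flatnonzero(np.nan_to_num(result.per_locus_fst, nan=-np.inf) > threshold)
    return pd.DataFrame(
        {
            "chrom": result.chrom[sel] if result.chrom is not None else sel,
            "pos": result.pos[sel] if result.pos is not None else sel,
            "locus_index": sel,
            "fst": result.per_locus_fst[sel],
        }
    )


# ------------------------------------------------------------------------ PCA

def genotype_pca(geno: GenotypeMatrix, n_components: int = 10, standardize: bool = False):
    """PCA of the sample x locus dosage matrix.

    Missing dosages are mean-imputed per locus; loci with more than 20%
    missing or zero variance are dropped; columns are centered (and
    optionally scaled by the binomial frequency standard deviation).
    Returns (coordinates, variance_fraction, n_loci_used).
    """
    from sklearn.decomposition import PCA

    if geno.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = geno.dosages.astype(float)
    x[x < 0] = np.nan
    miss = np.isnan(x).mean(axis=0)
    x = x[:, miss <= 0.2]
    col_mean = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(col_mean, idx[1])
    var = x.var(axis=0)
    keep = var > 0
    x = x[:, keep]
    x = x - x.mean(axis=0)
    if standardize:
        p = (col_mean[keep] / geno.ploidy.mean())
        sd = np.sqrt(np.maximum(p * (1 - p), 1e-12))
        x = x / sd
    n_comp = min(n_components, min(x.shape) - 1) or 1
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x)
    return coords, pca.explained_variance_ratio_, x.shape[1]


# ------------------------------------------------------------------ local PCA

@dataclass
class LocalPcaPartition:
    windows: pd.DataFrame  # chrom, start_bp, end_bp, n_loci, label
    distances: np.ndarray
    mds: np.ndarray
    outlier_labels: np.ndarray
    skipped_windows: int = 0


def classical_mds(d: np.ndarray, n_axes: int = 2) -> np.ndarray:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centers the squared distances, truncates negative eigenvalues at
    zero, and returns coordinates on the top ``n_axes`` axes ordered by
    eigenvalue.
    """
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals = np.maximum(vals[order], 0.0)
    vecs = vecs[:, order]
    coords = vecs[:, :n_axes] * np.sqrt(vals[:n_axes])
    return coords


def _window_summary(sub: np.ndarray, k: int) -> np.ndarray | None:
    """Rank-k eigen-summary of a window: normalized low-rank approximation of
    the sample covariance (eigenvalues scaled to unit total)."""
    x = sub.astype(float)
    x[x < 0] = np.nan
    col_mean = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(col_mean, idx[1])
    x = x - x.mean(axis=0)
    poly = (x.var(axis=0) > 0).sum()
    if poly < k + 1:
        return None
    cov = x @ x.T / max(x.shape[1] - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    vals_k = vals[order]
    total = vals.clip(min=0).sum()
    if total <= 0:
        return None
    vals_k = vals_k / total
    return (vecs[:, order] * vals_k) @ vecs[:, order].T


def local_pca_partition(geno: GenotypeMatrix, window_bp: int = 3000, k: int = 2,
                        n_axes: int = 2, window_snps: int | None = None,
                        mad_factor: float = 3.0) -> LocalPcaPartition:
    """Windowed local PCA with MDS over between-window distances.

    Windows are 3 kb genomic spans by default (or fixed SNP counts via
    ``window_snps``). Each window is summarized by the rank-``k``
    approximation of its sample covariance with eigenvalues normalized to
    unit total; window-window distance is the Frobenius norm between these
    summaries. Classical MDS embeds windows in ``n_axes`` dimensions.
    Outliers — windows farther than ``mad_factor`` median absolute deviations
    above the median distance to the medoid window — are grouped into at most
    3 clusters labeled LS1..LS3 by decreasing size.
    """
    bounds = []
    for chrom in pd.unique(geno.chrom):
        on = np.flatnonzero(geno.chrom == chrom)
        pos = geno.pos[on]
        if window_snps:
            for s in range(0, on.size, window_snps):
                sel = on[s : s + window_snps]
                bounds.append((chrom, int(pos[s]), int(geno.pos[sel[-1]]), sel))
        else:
            start = int(pos.min())
            stop = int(pos.max())
            for w0 in range(start, stop + 1, window_bp):
                sel = on[(pos >= w0) & (pos < w0 + window_bp)]
                if sel.size:
                    bounds.append((chrom, w0, w0 + window_bp - 1, sel))
    summaries, rows, skipped = [], [], 0
    for chrom, lo, hi, sel in bounds:
        summ = _window_summary(geno.dosages[:, sel], k)
        if summ is None:
            skipped += 1
            continue
        summaries.append(summ)
        rows.append({"chrom": chrom, "start_bp": lo, "end_bp": hi, "n_loci": int(sel.size)})
    if len(summaries) < 2:
        raise ValueError("fewer than 2 usable windows")
    n = len(summaries)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = np.linalg.norm(summaries[i] - summaries[j])
    mds = classical_mds(dist, n_axes)
    medoid = int(np.argmin(dist.sum(axis=1)))
    d_med = dist[medoid]
    med = np.median(d_med)
    mad = np.median(np.abs(d_med - med))
    labels = np.array(["none"] * n, dtype=object)
    if mad > 0:
        out_idx = np.flatnonzero(d_med > med + mad_factor * mad)
    elif (d_med > med).sum() < n / 2:
        # degenerate spread: most windows coincide with the medoid
        out_idx = np.flatnonzero(d_med > med)
    else:
        out_idx = np.array([], dtype=int)
    if out_idx.size == 1:
        labels[out_idx[0]] = "LS1"
    elif out_idx.size > 1:
        from scipy.cluster.hierarchy import fcluster, linkage

        # outlier windows within the outlier-detection distance scale of each
        # other belong to one cluster (single linkage), capped at 3 clusters
        link = linkage(dist[np.ix_(out_idx, out_idx)][np.triu_indices(out_idx.size, 1)],
                       method="single")
        scale = med + mad_factor * mad if mad > 0 else max(med, np.min(dist[dist > 0], initial=1.0))
        assign = fcluster(link, t=scale, criterion="distance")
        sizes = pd.Series(assign).value_counts()
        if len(sizes) > 3:
            # pool the smallest clusters into the third-largest one
            keep = set(sizes.index[:3])
            third = sizes.index[2]
            assign = np.array([a if a in keep else third for a in assign])
            sizes = pd.Series(assign).value_counts()
        rank = {clust: i + 1 for i, clust in enumerate(sizes.index)}
        for pos_i, clust in zip(out_idx, assign):
            labels[pos_i] = f"LS{rank[clust]}"
    windows = pd.DataFrame(rows)
    windows["label"] = labels
    return LocalPcaPartition(
        windows=windows, distances=dist, mds=mds, outlier_labels=labels,
        skipped_windows=skipped,
    )
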