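"""Synthetic dataset generators with recorded ground truth.

Every generator emulates one input of the analysis pipeline — per-site allele
depths under a known ploidy, a k-mer depth spectrum with planted genome size /
heterozygosity / repeat content, a TE annotation with planted solo/intact/decoy
labels, tandem-array and telomere-bearing sequences, paralog CDS pairs at a
planted synonymous distance, Balding-Nichols genotypes at a planted Fst, and
anchor sets with planted gene copy numbers. Each returns a ``(dataset,
SimTruth)`` pair; rerunning with the same seed reproduces both exactly. One
pseudo-random stream per call, seeded explicitly — no global state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io
from ._util import mutate_dna, random_dna
from .kmer_profile import KmerSpectrum
from .population_structure import GenotypeMatrix
from .truth import SimTruth

SOLO_RULES = ("length", "identity", "score", "shared_id_adjacency", "distance", "length_percentile")


# ------------------------------------------------------------- allele depths

def sim_allele_depths(ploidy: int, n_sites: int = 50_000, mean_depth: float = 60.0,
                      error_rate: float = 0.001, dosage_weights: dict | None = None,
                      seed: int = 0):
    """Simulate read depths at heterozygous biallelic sites of a polyploid.

    Per site the alternate-allele dosage ``g`` is drawn from ``1..ploidy-1``
    (uniform unless ``dosage_weights`` is given), total depth from
    Poisson(``mean_depth``), and alternate reads from Binomial(depth, p) with
    ``p = g/ploidy`` perturbed by the sequencing error rate. Sites without
    both alleles observed are dropped (they carry no heterozygous evidence).

    Returns a (table, truth) pair; the table has columns
    ``chrom, pos, ref_depth, alt_depth, qual``.
    """
    if ploidy not in (2, 3, 4):
        raise ValueError(f"unsupported ploidy {ploidy}; supported values are 2, 3, 4")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= error_rate < 0.05:
        raise ValueError("error_rate must be in [0, 0.05)")
    rng = np.random.default_rng(seed)
    classes = np.arange(1, ploidy)
    if dosage_weights is None:
        weights = np.full(classes.size, 1.0 / classes.size)
    else:
        weights = np.array([dosage_weights.get(int(c), 0.0) for c in classes], dtype=float)
        if not np.isclose(weights.sum(), 1.0):
            raise ValueError("dosage_weights must sum to 1 over dosages 1..ploidy-1")
    dosage = rng.choice(classes, size=n_sites, p=weights)
    depth = rng.poisson(mean_depth, n_sites)
    p_alt = dosage / ploidy
    p_obs = p_alt * (1 - error_rate) + (1 - p_alt) * error_rate
    alt = rng.binomial(depth, p_obs)
    ref = depth - alt
    pos = np.cumsum(rng.integers(50, 150, n_sites))
    qual = np.round(rng.uniform(30, 60, n_sites), 1)
    keep = (alt >= 1) & (ref >= 1)
    table = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos[keep],
            "ref_depth": ref[keep],
            "alt_depth": alt[keep],
            "qual": qual[keep],
        }
    )
    truth = SimTruth(
        "sim_allele_depths",
        seed,
        {
            "ploidy": ploidy,
            "n_sites": n_sites,
            "mean_depth": mean_depth,
            "error_rate": error_rate,
            "dosage_weights": {int(c): float(w) for c, w in zip(classes, weights)},
            "dosage": dosage[keep],
            "n_retained": int(keep.sum()),
        },
    )
    return table, truth


# -------------------------------------------------------------- k-mer spectrum

def _haplotypes(rng, genome_length_bp: int, heterozygosity: float,
                unit_len: int, repeat_copies: int):
    """Two haplotype strings: unique part + tandem unit copies, then mutation."""
    unique_len = genome_length_bp - unit_len * repeat_copies
    hap1 = random_dna(rng, unique_len) + random_dna(rng, unit_len) * repeat_copies
    hap2 = mutate_dna(hap1, heterozygosity, rng)
    return hap1, hap2


def sim_kmer_spectrum(genome_length_bp: int, heterozygosity: float = 0.0,
                      repeat_fraction: float = 0.0, k: int = 19,
                      mean_depth: float = 60.0, seed: int = 0,
                      repeat_copies: int = 10, error_kmer_factor: float = 0.5):
    """Simulate a k-mer depth histogram for a diploid genome.

    Two haplotypes are built at the stated per-base heterozygosity; a tandem
    duplication of ``repeat_copies`` identical copies realizes
    ``repeat_fraction`` of the haploid length. Canonical k-mers are counted
    exactly; the observed depth of each distinct k-mer is Poisson with mean
    (multiplicity across haplotypes) x (``mean_depth``/2), so homozygous
    single-copy k-mers peak at ``mean_depth`` and haplotype-specific ones at
    half that. A declining tail of low-depth error k-mers is added so the
    spectrum has the usual error valley.
    """
    if not 0 <= heterozygosity <= 0.05:
        raise ValueError("heterozygosity must be in [0, 0.05]")
    if not 0 <= repeat_fraction < 1:
        raise ValueError("repeat_fraction must be in [0, 1)")
    if k % 2 == 0 or not 15 <= k <= 31:
        raise ValueError("k must be odd and within [15, 31]")
    if genome_length_bp < 10 * k:
        raise ValueError(f"genome_length_bp must be at least 10*k = {10 * k}")
    rng = np.random.default_rng(seed)
    unit_len = int(round(repeat_fraction * genome_length_bp / repeat_copies))
    repeat_len = unit_len * repeat_copies
    hap1, hap2 = _haplotypes(rng, genome_length_bp, heterozygosity, unit_len, repeat_copies)
    from ._util import count_canonical_kmers

    _, mult = count_canonical_kmers([hap1, hap2], k)
    lam = mult * (mean_depth / 2.0)
    obs = rng.poisson(lam)
    n_err = int(error_kmer_factor * genome_length_bp)
    err = 1 + rng.poisson(0.3, n_err)
    depths_all = np.concatenate([obs[obs > 0], err])
    hist = np.bincount(depths_all)
    depths = np.flatnonzero(hist[1:]) + 1
    counts = hist[depths]
    spectrum = KmerSpectrum(k=k, depths=depths, counts=counts)
    truth = SimTruth(
        "sim_kmer_spectrum",
        seed,
        {
            "genome_length_bp": genome_length_bp,
            "heterozygosity_fraction": heterozygosity,
            "repeat_fraction": repeat_len / genome_length_bp,
            "repeat_copies": repeat_copies,
            "repeat_unit_bp": unit_len,
            "k": k,
            "mean_depth": mean_depth,
            "n_error_kmers": n_err,
        },
    )
    return spectrum, truth


# ------------------------------------------------------------ TE annotations

def _solo_record(rng, chrom, start, length, identity, score, name, method="homology"):
    return {
        "chrom": chrom,
        "source": "sim",
        "type": "long_terminal_repeat",
        "start": start,
        "end": start + length - 1,
        "score": float(score),
        "strand": rng.choice(["+", "-"]),
        "phase": ".",
        "attributes": {
            "ID": name,
            "Name": name,
            "Classification": "LTR/" + rng.choice(["Copia", "Gypsy"]),
            "Method": method,
            "Identity": f"{identity:.3f}",
        },
    }


def sim_te_gff(n_intact: int = 25, n_solo: int = 30, n_decoys: int = 6,
               chrom_length_bp: int = 5_000_000, seed: int = 0, n_other_te: int = 0):
    """Simulate a TE annotation with planted solo-LTR, intact, and decoy records.

    Intact LTR retrotransposons are emitted as a parent record with two
    ``long_terminal_repeat`` children and one internal child sharing the
    parent's element ID. Solo candidates are homology-method LTR records. Each
    decoy violates exactly one solo-LTR filter (cycling through
    ``SOLO_RULES``); the violated rule is recorded in the truth. True solos
    are placed with >= 5 kb clearance from every other LTR-related record.
    """
    rng = np.random.default_rng(seed)
    if n_intact < 1:
        raise ValueError("need at least one intact element (length percentile basis)")
    other_classes = ["DNA/Mutator", "DNA/CACTA", "MITE/Tourist", "LINE/unknown"]

    units = []  # each unit: list of record dicts with unit-relative starts
    candidates_truth = []
    ltr_lengths = []

    def intact_unit(idx):
        ltr_len = int(rng.integers(250, 401))
        internal_len = int(rng.integers(1500, 4001))
        ltr_lengths.append(ltr_len)
        elem_id = f"LTRRT{idx:05d}"
        ident = rng.uniform(0.90, 0.99)
        cls = "LTR/" + rng.choice(["Copia", "Gypsy"])
        total = 2 * ltr_len + internal_len
        strand = rng.choice(["+", "-"])
        recs = []
        attrs = {"ID": elem_id, "Name": f"TE_{idx:08d}", "Classification": cls,
                 "Method": "structural", "Identity": f"{ident:.3f}"}
        recs.append({"chrom": None, "source": "sim", "type": "LTR_retrotransposon",
                     "start": 0, "end": total - 1, "score": 1000.0, "strand": strand,
                     "phase": ".", "attributes": attrs})
        for part, (off, ln, ftype) in enumerate(
            [(0, ltr_len, "long_terminal_repeat"),
             (ltr_len, internal_len, "LTR_internal"),
             (ltr_len + internal_len, ltr_len, "long_terminal_repeat")]
        ):
            recs.append({"chrom": None, "source": "sim", "type": ftype, "start": off,
                         "end": off + ln - 1, "score": 1000.0, "strand": strand, "phase": ".",
                         "attributes": {"ID": f"{elem_id}_p{part}", "Parent": elem_id,
                                        "Classification": cls, "Method": "structural",
                                        "Identity": f"{ident:.3f}"}})
        return recs

    def fragment(parent_id, offset, length=300):
        return {"chrom": None, "source": "sim", "type": "LTR_internal", "start": offset,
                "end": offset + length - 1, "score": 500.0, "strand": "+", "phase": ".",
                "attributes": {"ID": parent_id + "_frag", "Parent": parent_id,
                               "Classification": "LTR/Copia", "Method": "structural",
                               "Identity": "0.900"}}

    serial = 0
    for _ in range(n_intact):
        units.append(intact_unit(serial))
        serial += 1
    for i in range(n_solo):
        name = f"SOLO{i:05d}"
        length = int(rng.integers(150, 251))
        rec = _solo_record(rng, None, 0, length, rng.uniform(0.85, 0.98),
                           rng.integers(400, 901), name)
        units.append([rec])
        candidates_truth.append({"id": name, "label": "solo", "rule": None})
    for i in range(n_decoys):
        rule = SOLO_RULES[i % len(SOLO_RULES)]
        name = f"DECOY{i:05d}"
        length = int(rng.integers(150, 251))
        identity = rng.uniform(0.85, 0.98)
        score = int(rng.integers(400, 901))
        if rule == "length":
            length = int(rng.integers(30, 100))
        elif rule == "identity":
            identity = rng.uniform(0.3, 0.79)
        elif rule == "score":
            score = int(rng.integers(50, 300))
        elif rule == "length_percentile":
            length = int(rng.integers(600, 900))  # above every intact LTR length
        unit = []
        offset = 0
        if rule == "shared_id_adjacency":
            frag_id = f"FRAGADJ{i:05d}"
            unit.append(fragment(frag_id, 0))
            offset = 300 + 6000
            unit.append(_solo_record(rng, None, offset, length, identity, score, name))
            unit.append(fragment(frag_id, offset + length - 1 + 6000 + 1))
        elif rule == "distance":
            unit.append(_solo_record(rng, None, 0, length, identity, score, name))
            unit.append(fragment(f"FRAGDIST{i:05d}", length - 1 + 2000 + 1))
        else:
            unit.append(_solo_record(rng, None, 0, length, identity, score, name))
        units.append(unit)
        candidates_truth.append({"id": name, "label": "decoy", "rule": rule})
    for i in range(n_other_te):
        cls = other_classes[i % len(other_classes)]
        length = int(rng.integers(200, 3000))
        units.append([{"chrom": None, "source": "sim", "type": "repeat_region", "start": 0,
                       "end": length - 1, "score": 800.0, "strand": rng.choice(["+", "-"]),
                       "phase": ".",
                       "attributes": {"ID": f"OTHER{i:05d}", "Name": f"TE_other_{i}",
                                      "Classification": cls, "Method": "homology",
                                      "Identity": f"{rng.uniform(0.8, 0.99):.3f}"}}])

    order = rng.permutation(len(units))
    rows = []
    cursor = 1
    for ui in order:
        unit = units[ui]
        gap = int(rng.integers(7000, 10001))
        base = cursor + gap
        span = max(r["end"] for r in unit) + 1
        if base + span > chrom_length_bp:
            raise ValueError(
                f"records do not fit on a {chrom_length_bp} bp chromosome with >=5 kb "
                f"spacing; increase chrom_length_bp"
            )
        for r in unit:
            r = dict(r, chrom="chr1", start=base + r["start"], end=base + r["end"])
            rows.append(r)
        cursor = base + span - 1
    gff = pd.DataFrame(rows, columns=io.GFF_COLUMNS).sort_values(
        ["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    truth = SimTruth(
        "sim_te_gff",
        seed,
        {
            "n_intact": n_intact,
            "n_solo": n_solo,
            "n_decoys": n_decoys,
            "candidates": candidates_truth,
            "intact_ltr_lengths": ltr_lengths,
            "chrom_length_bp": chrom_length_bp,
        },
    )
    return gff, truth


# ---------------------------------------------------------- repeat sequences

def sim_repeat_sequences(mode: str, monomer_or_motif, copies_or_tract: int,
                         divergence: float = 0.0, flank_bp: int = 5000, seed: int = 0,
                         hor_pattern: str | None = None, hor_divergence: float = 0.01):
    """Simulate a tandem satellite array or a telomere-bearing sequence.

    ``tandem`` mode concatenates ``copies_or_tract`` mutated copies of the
    monomer between random flanks; an optional ``hor_pattern`` such as ``"AB"``
    cycles distinct monomer variants to plant a higher-order repeat. In
    ``telomere`` mode a terminal motif tract of ``copies_or_tract`` bp
    (rounded down to whole motif copies) is placed at the 3' end; the two
    motif-lengths of flank adjacent to the tract are forced to mismatch the
    periodic continuation so the planted tract length is exact.
    """
    if divergence > 0.1:
        raise ValueError("divergence must be <= 0.1")
    rng = np.random.default_rng(seed)
    if mode == "tandem":
        monomer = (random_dna(rng, monomer_or_motif)
                   if isinstance(monomer_or_motif, (int, np.integer)) else str(monomer_or_motif).upper())
        if len(monomer) < 6:
            raise ValueError("monomer length must be >= 6")
        pattern = hor_pattern or "A"
        variants = {}
        for letter in dict.fromkeys(pattern):
            if letter == pattern[0]:
                variants[letter] = monomer
            else:
                var = mutate_dna(monomer, hor_divergence, rng)
                while var == monomer:
                    var = mutate_dna(monomer, max(hor_divergence, 1.5 / len(monomer)), rng)
                variants[letter] = var
        copies = int(copies_or_tract)
        array = "".join(variants[pattern[i % len(pattern)]] for i in range(copies))
        array = mutate_dna(array, divergence, rng)
        seq = random_dna(rng, flank_bp) + array + random_dna(rng, flank_bp)
        truth = SimTruth(
            "sim_repeat_sequences",
            seed,
            {
                "mode": "tandem",
                "monomer_length_bp": len(monomer),
                "monomer": monomer,
                "copies": copies,
                "divergence": divergence,
                "hor_pattern": pattern,
                "hor_period_bp": len(pattern) * len(monomer) if len(pattern) > 1 else None,
                "array_start": flank_bp + 1,
                "array_end": flank_bp + len(array),
            },
        )
        return {"tandem_array": seq}, truth
    if mode == "telomere":
        motif = str(monomer_or_motif).upper()
        if len(motif) < 6:
            raise ValueError("motif length must be >= 6")
        m = len(motif)
        copies = int(copies_or_tract) // m
        tract = mutate_dna(motif * copies, divergence, rng)
        flank = list(random_dna(rng, flank_bp))
        # guard: force the two motif-lengths of flank next to the tract to
        # mismatch the inward periodic continuation at every base
        for j in range(1, min(2 * m, flank_bp) + 1):
            expected = motif[(-j) % m]
            if flank[-j] == expected:
                flank[-j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[expected]
        seq = "".join(flank) + tract
        truth = SimTruth(
            "sim_repeat_sequences",
            seed,
            {
                "mode": "telomere",
                "motif": motif,
                "tract_length_bp": copies * m,
                "copies": copies,
                "divergence": divergence,
                "end": "3p",
            },
        )
        return {"telomere_seq": seq}, truth
    raise ValueError(f"unknown mode {mode!r}; expected 'tandem' or 'telomere'")


# -------------------------------------------------------------- paralog CDS

_FOURFOLD_PREFIXES = ("GC", "GG", "CC", "AC", "GT", "TC")
_BASES = "ACGT"


def sim_paralog_cds(n_pairs: int, ks_targets, n_codons: int = 500, seed: int = 0):
    """Simulate paralogous CDS pairs at planted synonymous distances.

    Sequences are built from fourfold-degenerate codon families, so every
    substitution applied at a third position is synonymous and no stop codons
    can arise. For each pair the number of substituted codons is searched so
    the realized Nei-Gojobori Ks is within 0.01 of the target; the realized
    value is recorded in the truth.
    """
    from .wgm_synteny import compute_ks

    ks_targets = list(ks_targets)
    if len(ks_targets) not in (1, n_pairs):
        raise ValueError("ks_targets must have length 1 or n_pairs")
    if len(ks_targets) == 1:
        ks_targets = ks_targets * n_pairs
    if any(not 0 <= t <= 2 for t in ks_targets):
        raise ValueError("ks_targets values must lie in [0, 2]")
    if n_codons < 100:
        raise ValueError("n_codons must be >= 100")
    rng = np.random.default_rng(seed)
    pairs = {}
    realized = []
    for i, target in enumerate(ks_targets):
        prefixes = rng.choice(len(_FOURFOLD_PREFIXES), n_codons)
        thirds = rng.integers(0, 4, n_codons)
        codons = [_FOURFOLD_PREFIXES[p] + _BASES[t] for p, t in zip(prefixes, thirds)]
        seq_a = "".join(codons)
        order = rng.permutation(n_codons)
        shifts = rng.integers(1, 4, n_codons)

        def build(n_changes):
            out = list(codons)
            for idx in order[:n_changes]:
                c = out[idx]
                out[idx] = c[:2] + _BASES[(_BASES.index(c[2]) + shifts[idx]) % 4]
            return "".join(out)

        lo, hi = 0, n_codons
        best_n, best_err = 0, abs(compute_ks(seq_a, seq_a).ks - target)
        while lo <= hi:
            mid = (lo + hi) // 2
            ks = compute_ks(seq_a, build(mid)).ks
            err = abs(ks - target)
            if err < best_err:
                best_n, best_err = mid, err
            if ks < target:
                lo = mid + 1
            else:
                hi = mid - 1
        seq_b = build(best_n)
        ks_real = compute_ks(seq_a, seq_b).ks
        if abs(ks_real - target) > 0.01:
            raise ValueError(
                f"ks target {target} unreachable within 0.01 with {n_codons} codons "
                f"(closest realized {ks_real:.4f}); increase n_codons"
            )
        pairs[f"pair{i:04d}"] = (seq_a, seq_b)
        realized.append(ks_real)
    truth = SimTruth(
        "sim_paralog_cds",
        seed,
        {"n_pairs": n_pairs, "n_codons": n_codons, "ks_targets": ks_targets,
         "ks_values": realized},
    )
    return pairs, truth


# ------------------------------------------------------ Balding-Nichols SNPs

def sim_genotypes_bn(n_pops: int = 2, n_per_pop: int = 30, n_loci: int = 2000,
                     fst: float = 0.2, ploidy: int = 2, maf_floor: float = 0.05,
                     seed: int = 0, locus_spacing_bp: int = 50):
    """Simulate genotype dosages under the Balding-Nichols model.

    Ancestral frequencies are uniform on [maf_floor, 1-maf_floor]; each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), whose F parameter
    equals the expected Weir-Cockerham Fst; dosages are Binomial(ploidy, p_pop).
    """
    if not 0 < fst < 1:
        raise ValueError("fst must lie strictly between 0 and 1 (Beta parameters degenerate)")
    if ploidy not in (2, 4):
        raise ValueError("ploidy must be 2 or 4")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(maf_floor, 1 - maf_floor, n_loci)
    scale = (1 - fst) / fst
    n_samples = n_pops * n_per_pop
    dosages = np.empty((n_samples, n_loci), dtype=np.int8)
    pop_freqs = np.empty((n_pops, n_loci))
    pops = []
    for p in range(n_pops):
        pf = rng.beta(p_anc * scale, (1 - p_anc) * scale)
        pop_freqs[p] = pf
        rows = slice(p * n_per_pop, (p + 1) * n_per_pop)
        dosages[rows] = rng.binomial(ploidy, pf, size=(n_per_pop, n_loci))
        pops.extend([f"pop{p + 1}"] * n_per_pop)
    geno = GenotypeMatrix(
        dosages=dosages,
        samples=[f"s{i:03d}" for i in range(n_samples)],
        ploidy=np.full(n_samples, ploidy),
        populations=np.array(pops),
        chrom=np.array(["1"] * n_loci),
        pos=np.arange(1, n_loci + 1) * locus_spacing_bp,
    )
    truth = SimTruth(
        "sim_genotypes_bn",
        seed,
        {"n_pops": n_pops, "n_per_pop": n_per_pop, "n_loci": n_loci, "fst": fst,
         "ploidy": ploidy, "maf_floor": maf_floor},
    )
    return geno, truth


# --------------------------------------------------------------- anchor sets

def sim_anchor_sets(n_genes: int = 4000, copy_number_probs: dict | None = None,
                    shuffle_rate: float = 0.0, seed: int = 0, segment_genes: int = 40):
    """Simulate a synteny anchor set with planted per-gene copy numbers.

    The query genome is one chromosome of ``n_genes`` ordered genes, split
    into segments of ``segment_genes`` consecutive genes. Each segment gets a
    copy number c drawn from ``copy_number_probs`` (keys 0..5; largest-
    remainder allocation so realized class fractions match the probabilities),
    and its genes are laid out as c collinear runs on target chromosomes
    t1..tc. A ``shuffle_rate`` fraction of anchors is transposed to random
    target positions as noise. Segment length exceeds the default chaining
    gap limit, so runs from different segments on a shared target chromosome
    break into separate blocks wherever a segment skips that chromosome.
    """
    if copy_number_probs is None:
        copy_number_probs = {1: 1.0}
    probs = {int(k): float(v) for k, v in copy_number_probs.items()}
    if any(k < 0 or k > 5 for k in probs):
        raise ValueError("copy numbers must lie in 0..5")
    if not np.isclose(sum(probs.values()), 1.0):
        raise ValueError("copy_number_probs must sum to 1")
    rng = np.random.default_rng(seed)
    n_segments = int(np.ceil(n_genes / segment_genes))
    # largest-remainder allocation of segments to copy-number classes
    keys = sorted(probs)
    ideal = np.array([probs[k] * n_segments for k in keys])
    alloc = np.floor(ideal).astype(int)
    rem = ideal - alloc
    for idx in np.argsort(-rem)[: n_segments - alloc.sum()]:
        alloc[idx] += 1
    seg_copy = np.repeat(keys, alloc)
    seg_copy = seg_copy[rng.permutation(n_segments)]

    gene_copy = np.zeros(n_genes, dtype=int)
    cursors = {f"t{i}": 0 for i in range(1, 6)}
    rows = []
    for s, c in enumerate(seg_copy):
        genes = np.arange(s * segment_genes, min((s + 1) * segment_genes, n_genes))
        gene_copy[genes] = c
        for level in range(1, c + 1):
            chrom = f"t{level}"
            for g in genes:
                rows.append((f"g{g:05d}", f"h_{chrom}_{cursors[chrom]:05d}", 100.0,
                             "q1", int(g), chrom, cursors[chrom]))
                cursors[chrom] += 1
    anchors = pd.DataFrame(rows, columns=io.ANCHOR_COLUMNS)
    shuffled = np.zeros(len(anchors), dtype=bool)
    if shuffle_rate > 0 and len(anchors):
        shuffled = rng.random(len(anchors)) < shuffle_rate
        idx = np.flatnonzero(shuffled)
        anchors.loc[idx, "chromB"] = [f"t{t}" for t in rng.integers(1, 6, idx.size)]
        anchors.loc[idx, "posB"] = rng.integers(10 * n_genes, 20 * n_genes, idx.size)
    truth = SimTruth(
        "sim_anchor_sets",
        seed,
        {
            "n_genes": n_genes,
            "segment_genes": segment_genes,
            "copy_number_probs": probs,
            "per_gene_copy_number": gene_copy,
            "class_fractions": {int(k): float(np.mean(gene_copy == k)) for k in range(6)},
            "shuffle_rate": shuffle_rate,
            "shuffled_mask": shuffled,
        },
    )
    return anchors, truth
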