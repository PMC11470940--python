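"""Solo-LTR classification, solo:intact ratios, insertion ages, TE summaries.

A solo LTR is the single long terminal repeat left behind when intra-element
recombination excises an LTR retrotransposon; a high solo:intact ratio
signals active genome purging after polyploidy. Candidates (homology-method
LTR annotations) are accepted as solo only if they pass, in order:

1. length   — at least 100 bp;
2. identity — at least 0.8 to the reference LTR;
3. score    — alignment score at least 300 (read from the annotation);
4. shared_id_adjacency — the four nearest flanking LTR-RT annotations (two
   per side on the same chromosome) must not share one element ID across
   sides (a shared ID means the candidate sits inside a fragmented element);
5. distance — at least 5000 bp to the nearest solo candidate, intact LTR, or
   internal sequence;
6. length_percentile — no longer than the 95th percentile of the LTR lengths
   of intact elements (computed genome-wide).

The first violated rule is recorded per candidate. Insertion ages come from
the divergence of an element's two LTRs, Jukes-Cantor corrected by default,
at a substitution rate of 4.72e-9 per site per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import interval_union_length
from .io import read_gff3

DEFAULT_LTR_RATE = 4.72e-9
RULES = ("length", "identity", "score", "shared_id_adjacency", "distance", "length_percentile")

MIN_LENGTH = 100
MIN_IDENTITY = 0.8
MIN_SCORE = 300
MIN_DISTANCE = 5000
LENGTH_PERCENTILE = 95


@dataclass
class TEAnnotationSet:
    """TE records with derived roles, backed by a GFF3-style DataFrame.

    Roles: ``intact`` (parent LTR-RT record), ``ltr`` (terminal repeat of an
    intact element), ``internal`` (internal sequence), ``candidate``
    (homology-method LTR record, potential solo), ``other``.
    """

    records: pd.DataFrame

    @classmethod
    def from_gff3(cls, path) -> "TEAnnotationSet":
        return cls.from_frame(read_gff3(path))

    @classmethod
    def from_frame(cls, gff: pd.DataFrame) -> "TEAnnotationSet":
        df = gff.copy()
        attrs = df["attributes"]
        df["te_id"] = [a.get("ID", "") for a in attrs]
        df["ltr_rt_id"] = [a.get("Parent", a.get("ID", "")) for a in attrs]
        df["method"] = [a.get("Method", "").lower() for a in attrs]
        df["te_class"] = [a.get("Classification", "other") for a in attrs]
        identity = []
        for a in attrs:
            try:
                identity.append(float(a["Identity"]))
            except (KeyError, ValueError):
                identity.append(np.nan)  # absent identity fails the identity rule
        df["identity"] = identity
        df["length"] = df["end"] - df["start"] + 1
        if (df["start"] > df["end"]).any():
            raise ValueError("record with start > end")
        roles = []
        for row in df.itertuples(index=False):
            has_parent = "Parent" in row.attributes
            if row.type == "LTR_retrotransposon" and not has_parent:
                roles.append("intact")
            elif row.type == "long_terminal_repeat" and has_parent:
                roles.append("ltr")
            elif row.type in ("LTR_internal", "LTR_internal_sequence"):
                roles.append("internal")
            elif row.type == "long_terminal_repeat" and row.method == "homology":
                roles.append("candidate")
            else:
                roles.append("other")
        df["role"] = roles
        return cls(df.reset_index(drop=True))

    def by_role(self, *roles) -> pd.DataFrame:
        return self.records[self.records["role"].isin(roles)]


@dataclass
class SoloLtrReport:
    """Per-candidate verdicts and per-chromosome solo/intact tallies."""

    verdicts: pd.DataFrame  # te_id, chrom, start, end, verdict ('solo' or rule)
    length_bound: float | None
    warnings: list = field(default_factory=list)
    intact_counts: pd.Series = None
    solo_counts: pd.Series = None

    @property
    def solos(self) -> pd.DataFrame:
        return self.verdicts[self.verdicts["verdict"] == "solo"]


def classify_solo_ltrs(annotation: TEAnnotationSet) -> SoloLtrReport:
    """Apply the six solo-LTR filters to every homology-method candidate."""
    df = annotation.records
    candidates = annotation.by_role("candidate")
    intact_ltrs = annotation.by_role("ltr")
    warnings_list = []
    if len(intact_ltrs):
        bound = float(np.percentile(intact_ltrs["length"], LENGTH_PERCENTILE))
    else:
        bound = None
        warnings_list.append("no intact LTRs: length-percentile rule skipped")

    # neighbors carrying an element id (intact parents, their LTRs, internals)
    id_carriers = df[df["role"].isin(("intact", "ltr", "internal"))]
    # records that count for the distance rule
    distance_targets = df[df["role"].isin(("candidate", "ltr", "internal"))]

    verdicts = []
    for cand in candidates.itertuples():
        verdict = "solo"
        if cand.length < MIN_LENGTH:
            verdict = "length"
        elif not (cand.identity >= MIN_IDENTITY):  # NaN identity fails
            verdict = "identity"
        elif not (cand.score >= MIN_SCORE):
            verdict = "score"
        else:
            chrom_ids = id_carriers[id_carriers["chrom"] == cand.chrom]
            up = chrom_ids[chrom_ids["end"] < cand.start].nlargest(2, "end")
            down = chrom_ids[chrom_ids["start"] > cand.end].nsmallest(2, "start")
            if set(up["ltr_rt_id"]) & set(down["ltr_rt_id"]):
                verdict = "shared_id_adjacency"
            else:
                near = distance_targets[
                    (distance_targets["chrom"] == cand.chrom)
                    & (distance_targets.index != cand.Index)
                ]
                if len(near):
                    gap = np.maximum(
                        near["start"].to_numpy() - cand.end - 1,
                        cand.start - near["end"].to_numpy() - 1,
                    )
                    gap = np.maximum(gap, 0)  # overlapping records: distance 0
                    if gap.min() < MIN_DISTANCE:
                        verdict = "distance"
                if verdict == "solo" and bound is not None and cand.length > bound:
                    verdict = "length_percentile"
        verdicts.append((cand.te_id, cand.chrom, cand.start, cand.end, verdict))
    vdf = pd.DataFrame(verdicts, columns=["te_id", "chrom", "start", "end", "verdict"])
    intact = annotation.by_role("intact")
    return SoloLtrReport(
        verdicts=vdf,
        length_bound=bound,
        warnings=warnings_list,
        intact_counts=intact.groupby("chrom").size() if len(intact) else pd.Series(dtype=int),
        solo_counts=(vdf[vdf["verdict"] == "solo"].groupby("chrom").size()
                     if len(vdf) else pd.Series(dtype=int)),
    )


def solo_intact_ratio(report: SoloLtrReport, by: str = "genome") -> pd.DataFrame:
    """Solo:intact ratio per chromosome or genome-wide.

    Groups with zero intact elements are flagged undefined rather than
    divided.
    """
    if by not in ("chromosome", "genome"):
        raise ValueError("by must be 'chromosome' or 'genome'")
    solos = report.solo_counts if report.solo_counts is not None else pd.Series(dtype=int)
    intacts = report.intact_counts if report.intact_counts is not None else pd.Series(dtype=int)
    if by == "genome":
        s, n = int(solos.sum()), int(intacts.sum())
        return pd.DataFrame(
            [{"group": "genome", "solo": s, "intact": n,
              "ratio": s / n if n else np.nan, "undefined": n == 0}]
        )
    chroms = sorted(set(solos.index) | set(intacts.index))
    rows = []
    for chrom in chroms:
        s = int(solos.get(chrom, 0))
        n = int(intacts.get(chrom, 0))
        rows.append({"group": chrom, "solo": s, "intact": n,
                     "ratio": s / n if n else np.nan, "undefined": n == 0})
    return pd.DataFrame(rows)


@dataclass
class InsertionAge:
    divergence_raw: float
    divergence_corrected: float
    age_years: float
    rate_per_site_per_year: float
    aligned_sites: int


def ltr_insertion_age(ltr5_seq: str, ltr3_seq: str, rate: float = DEFAULT_LTR_RATE,
                      jukes_cantor: bool = True) -> InsertionAge:
    """Estimate element insertion age from the divergence of its two LTRs.

    The LTRs are identical at insertion, so their divergence d accumulated at
    rate mu per site per year gives age T = d / (2 mu). Divergence is the
    p-distance over aligned non-gap columns of a global alignment,
    Jukes-Cantor corrected (``d = -3/4 ln(1 - 4p/3)``) unless
    ``jukes_cantor=False``.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=-1, open_gap_score=-2,
                                    extend_gap_score=-0.5)
    aln = aligner.align(ltr5_seq.upper(), ltr3_seq.upper())[0]
    a, b = str(aln[0]), str(aln[1])
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        raise ValueError("no aligned non-gap columns")
    n_diff = sum(x != y for x, y in pairs)
    p = n_diff / len(pairs)
    if jukes_cantor:
        if p >= 0.75:
            raise ValueError("saturated divergence: p >= 0.75, Jukes-Cantor undefined")
        d = max(0.0, -0.75 * np.log(1 - 4 * p / 3))
    else:
        d = p
    return InsertionAge(
        divergence_raw=p,
        divergence_corrected=d,
        age_years=d / (2 * rate),
        rate_per_site_per_year=rate,
        aligned_sites=len(pairs),
    )


def te_summary(annotation: TEAnnotationSet, genome_length_bp: int) -> pd.DataFrame:
    """Per-class record counts, merged bp covered, and percent of genome."""
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    df = annotation.records
    beyond = df[df["end"] > genome_length_bp]
    if len(beyond):
        bad = beyond.iloc[0]
        raise ValueError(
            f"record {bad['te_id']} ({bad['chrom']}:{bad['start']}-{bad['end']}) "
            f"extends beyond genome length {genome_length_bp}"
        )
    rows = []
    for te_class, sub in df.groupby("te_class"):
        covered = 0
        for _, chrom_sub in sub.groupby("chrom"):
            covered += interval_union_length(
                chrom_sub["start"].to_numpy(), chrom_sub["end"].to_numpy()
            )
        rows.append({"te_class": te_class, "n_records": len(sub), "bp_covered": covered,
                     "percent_of_genome": 100.0 * covered / genome_length_bp})
    out = pd.DataFrame(rows).sort_values("bp_covered", ascending=False).reset_index(drop=True)
    total_bp = sum(
        interval_union_length(sub["start"].to_numpy(), sub["end"].to_numpy())
        for _, sub in df.groupby("chrom")
    )
    out.attrs["total_bp_covered"] = total_bp
    out.attrs["total_percent"] = 100.0 * total_bp / genome_length_bp
    return out
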