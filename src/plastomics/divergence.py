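"""Reference-projected alignment, SNP calling and divergence proportions.

Each query genome is globally aligned to a designated reference and its
alleles are projected onto reference coordinates: one allele per reference
position, ``-`` marking a deletion, with insertions kept aside as
``(ref_position, inserted_string)`` pairs.  SNPs are substitution-only:
a reference position is variable iff at least one taxon carries a non-gap,
non-N allele different from the reference base.  Divergence proportions are
SNP counts over partition lengths, expressed as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .genome_io import PlastomeRecord, revcomp

__all__ = [
    "ProjectedAlignment",
    "SnpTable",
    "DivergenceSummary",
    "align_to_reference",
    "call_snps",
    "summarize_divergence",
    "sliding_identity",
]


@dataclass
class ProjectedAlignment:
    """A query genome expressed in reference coordinates."""

    taxon_id: str
    alleles: np.ndarray  # length == reference length, dtype '<U1'
    insertions: list[tuple[int, str]] = field(default_factory=list)
    edit_distance: int = 0

    @property
    def identity(self) -> float:
        """Fraction of matching non-gap, non-N reference columns."""
        valid = ~np.isin(self.alleles, ("-", "N"))
        return float(self._matches[valid].mean()) if valid.any() else 0.0

    # set by align_to_reference
    _matches: np.ndarray = field(default=None, repr=False)


def _parse_cigar(cigar: str):
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            yield num, ch
            num = 0


def align_to_reference(
    reference: PlastomeRecord,
    query: PlastomeRecord,
    min_identity: float = 0.70,
    try_revcomp: bool = True,
) -> ProjectedAlignment:
    """Global pairwise alignment of ``query`` onto ``reference`` coordinates.

    Both records are expected in canonical rotation.  The reverse complement
    of the query is tried as well (unless disabled) and the orientation with
    the smaller edit distance is kept.  Deterministic for fixed inputs.

    Raises ``ValueError`` when the aligned identity falls below
    ``min_identity`` — the genomes are too divergent for projection.
    """
    ref_seq = reference.sequence
    qry_seq = query.sequence
    res = edlib.align(qry_seq, ref_seq, mode="NW", task="path")
    if try_revcomp:
        rc = revcomp(qry_seq)
        res_rc = edlib.align(rc, ref_seq, mode="NW", task="path")
        if res_rc["editDistance"] < res["editDistance"]:
            res, qry_seq = res_rc, rc
    n = len(ref_seq)
    alleles = np.empty(n, dtype="<U1")
    matches = np.zeros(n, dtype=bool)
    qcol = np.full(n, -1, dtype=np.int64)  # query index aligned per column
    insertions: list[tuple[int, str]] = []
    dirty: list[int] = []  # columns touched by indel events
    ri = qi = 0
    for length, op in _parse_cigar(res["cigar"]):
        if op in ("=", "X", "M"):
            chunk = qry_seq[qi : qi + length]
            alleles[ri : ri + length] = list(chunk)
            matches[ri : ri + length] = [
                a == b for a, b in zip(chunk, ref_seq[ri : ri + length])
            ]
            qcol[ri : ri + length] = np.arange(qi, qi + length)
            ri += length
            qi += length
        elif op == "D":  # consumes reference only: deletion in query
            alleles[ri : ri + length] = "-"
            dirty.extend(range(ri, ri + length))
            ri += length
        elif op == "I":  # consumes query only: insertion relative to reference
            insertions.append((ri, qry_seq[qi : qi + length]))
            dirty.append(min(ri, n - 1))
            qi += length
        else:  # pragma: no cover - edlib emits only =, X, M, I, D
            raise ValueError(f"unexpected CIGAR op {op!r}")
    assert ri == n and qi == len(qry_seq)
    if dirty:
        alleles, matches, insertions = _polish_indels(
            ref_seq, qry_seq, alleles, matches, qcol, insertions, dirty
        )
    proj = ProjectedAlignment(
        taxon_id=query.taxon_id,
        alleles=alleles,
        insertions=insertions,
        edit_distance=int(res["editDistance"]),
    )
    proj._matches = matches
    ident = proj.identity
    if ident < min_identity:
        raise ValueError(
            f"{query.taxon_id}: aligned identity {ident:.2f} below "
            f"{min_identity:.2f}; genomes too divergent for projection"
        )
    return proj


_MATCH, _MISMATCH, _GAP = 0, 4, 5  # gap pair (10) dearer than 2 mismatches (8)


def _realign_chunk(ref: str, qry: str) -> tuple[list[str], list[tuple[int, str]]]:
    """Needleman–Wunsch with substitutions preferred over gap pairs.

    Returns per-reference-position alleles and (offset, string) insertions
    for the chunk.  Tie-break order: diagonal, deletion, insertion.
    """
    nr, nq = len(ref), len(qry)
    qarr = np.frombuffer(qry.encode(), dtype="S1")
    jgap = np.arange(nq + 1) * _GAP
    dp = np.empty((nr + 1, nq + 1), dtype=np.int64)
    dp[0, :] = jgap
    for i in range(1, nr + 1):
        row = dp[i]
        sub = dp[i - 1, :-1] + np.where(qarr == ref[i - 1].encode(), _MATCH, _MISMATCH)
        row[0] = i * _GAP
        row[1:] = np.minimum(sub, dp[i - 1, 1:] + _GAP)
        # close the left-gap (insertion) transitions within the row
        tmp = row - jgap
        np.minimum.accumulate(tmp, out=tmp)
        row[:] = tmp + jgap
    alleles = [""] * nr
    ins_map: dict[int, list[str]] = {}
    i, j = nr, nq
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            cost = _MATCH if ref[i - 1] == qry[j - 1] else _MISMATCH
            if dp[i, j] == dp[i - 1, j - 1] + cost:
                alleles[i - 1] = qry[j - 1]
                i, j = i - 1, j - 1
                continue
        if i > 0 and dp[i, j] == dp[i - 1, j] + _GAP:
            alleles[i - 1] = "-"
            i -= 1
            continue
        ins_map.setdefault(i, []).append(qry[j - 1])
        j -= 1
    inss = sorted(
        (pos, "".join(reversed(chars))) for pos, chars in ins_map.items()
    )
    return alleles, inss


def _polish_indels(ref_seq, qry_seq, alleles, matches, qcol, insertions, dirty):
    """Re-align small windows around indel events, anchored on clean match
    columns, so equal-cost del+ins pairs become substitution columns."""
    n = len(ref_seq)
    anchor = matches & (qcol >= 0)
    # cluster dirty columns, expand each cluster to clean anchor columns,
    # then merge overlapping expanded windows
    clusters: list[tuple[int, int]] = []
    for p in sorted(set(dirty)):
        if clusters and p <= clusters[-1][1] + 8:
            clusters[-1] = (clusters[-1][0], p)
        else:
            clusters.append((p, p))
    expanded: list[tuple[int, int]] = []
    for a, b in clusters:
        la = a - 1
        while la >= 0 and not anchor[la]:
            la -= 1
        rb = b + 1
        while rb < n and not anchor[rb]:
            rb += 1
        if expanded and la + 1 <= expanded[-1][1]:
            expanded[-1] = (expanded[-1][0], rb)
        else:
            expanded.append((la + 1, rb))
    new_insertions = list(insertions)
    for r_lo, r_hi in expanded:
        q_lo = int(qcol[r_lo - 1]) + 1 if r_lo > 0 else 0
        q_hi = int(qcol[r_hi]) if r_hi < n else len(qry_seq)
        sub_alleles, sub_ins = _realign_chunk(
            ref_seq[r_lo:r_hi], qry_seq[q_lo:q_hi]
        )
        for off, al in enumerate(sub_alleles):
            alleles[r_lo + off] = al
            matches[r_lo + off] = al == ref_seq[r_lo + off]
        new_insertions = [
            (ri, s) for ri, s in new_insertions if not (r_lo <= ri <= r_hi)
        ]
        new_insertions.extend((r_lo + off, s) for off, s in sub_ins)
    new_insertions.sort()
    return alleles, matches, new_insertions


def _safe_col(taxon: str) -> str:
    out = "".join(c if c.isalnum() else "_" for c in taxon)
    return out if out[:1].isalpha() else "t_" + out


@dataclass
class SnpTable:
    """Reference-anchored substitution table.

    ``df`` columns: ``pos`` (0-based, unique, sorted), ``ref``, one
    (sanitised) column per taxon, ``n_alleles`` and ``region_class``.
    """

    reference_id: str
    taxa: list[str]
    df: pd.DataFrame

    @property
    def total_snps(self) -> int:
        return len(self.df)

    def to_tsv(self, path) -> None:
        header = (
            f"# SNPs vs reference {self.reference_id}; positions 0-based; "
            "percentages elsewhere use partition lengths as denominators\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.df.to_csv(fh, sep="\t", index=False)


def call_snps(
    reference: PlastomeRecord,
    projections: list[ProjectedAlignment],
) -> SnpTable:
    """Substitution-only SNP calling over projected alignments.

    A reference position becomes a row iff at least one taxon has a non-gap,
    non-N allele differing from the reference base; indel-only and N-only
    differences are excluded, and multi-allelic positions collapse to one
    row with ``n_alleles`` counting distinct observed alleles (reference
    included).
    """
    n = reference.length_bp
    ref = np.frombuffer(reference.sequence.encode("ascii"), dtype="S1").astype("<U1")
    taxa = [p.taxon_id for p in projections]
    mat = np.vstack([p.alleles for p in projections]) if projections else np.empty((0, n), dtype="<U1")
    informative = (mat != "-") & (mat != "N")
    is_snp = ((mat != ref) & informative).any(axis=0)
    # positions where the reference itself is N never count
    is_snp &= ref != "N"
    pos = np.flatnonzero(is_snp)
    rows = {
        "pos": pos,
        "ref": ref[pos],
    }
    for i, t in enumerate(taxa):
        rows[_safe_col(t)] = mat[i, pos]
    n_alleles = []
    for j, p in enumerate(pos):
        obs = {ref[p]}
        col = mat[:, p]
        obs.update(a for a in col[informative[:, p]])
        n_alleles.append(len(obs))
    rows["n_alleles"] = np.asarray(n_alleles, dtype=int)
    rows["region_class"] = np.full(pos.size, "unassigned", dtype=object)
    df = pd.DataFrame(rows)
    return SnpTable(reference_id=reference.taxon_id, taxa=taxa, df=df)


def classify_snps(snps: SnpTable, partition) -> SnpTable:
    """Assign each SNP row its partition class (coding/intron/spacer)."""
    cls = partition.class_of_positions(snps.df["pos"].to_numpy())
    snps.df["region_class"] = cls
    return snps


@dataclass(frozen=True)
class DivergenceSummary:
    """Cohort divergence proportions by partition (percent of bp)."""

    total_snps: int
    total_pct: float
    coding_snps: int
    coding_pct: float | None
    noncoding_snps: int
    noncoding_pct: float | None

    def as_dict(self) -> dict:
        return {
            "total_snps": self.total_snps,
            "total_pct": self.total_pct,
            "coding_snps": self.coding_snps,
            "coding_pct": self.coding_pct,
            "noncoding_snps": self.noncoding_snps,
            "noncoding_pct": self.noncoding_pct,
        }


def summarize_divergence(
    snps: SnpTable, partition, reference_length: int
) -> DivergenceSummary:
    """Divergence proportions: SNP counts over partition lengths.

    ``total_pct`` uses the full reference length as denominator; coding and
    non-coding (introns + spacers pooled) percentages use their partition
    lengths.  A zero-length partition reports ``None`` (undefined), not 0.
    """
    snps = classify_snps(snps, partition)
    cls = snps.df["region_class"]
    coding = int((cls == "coding").sum())
    noncoding = int(cls.isin(["intron", "spacer"]).sum())
    total = snps.total_snps
    nc_len = partition.intron_length + partition.spacer_length

    def pct(count: int, length: int) -> float | None:
        return None if length == 0 else 100.0 * count / length

    return DivergenceSummary(
        total_snps=total,
        total_pct=pct(total, reference_length),
        coding_snps=coding,
        coding_pct=pct(coding, partition.coding_length),
        noncoding_snps=noncoding,
        noncoding_pct=pct(noncoding, nc_len),
    )


def sliding_identity(
    reference: PlastomeRecord,
    projections: list[ProjectedAlignment],
    window: int = 100,
    step: int = 25,
) -> pd.DataFrame:
    """Per-window identity of each taxon against the reference.

    Identity is the fraction of matching non-gap columns in the window; a
    window with no non-gap columns for a taxon reports NA.  A window longer
    than the genome collapses to a single whole-genome window.
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    n = reference.length_bp
    if window > n:
        window, step = n, n
    starts = list(range(0, max(1, n - window + 1), step))
    rows = []
    for p in projections:
        nongap = p.alleles != "-"
        match = p._matches
        cs_gap = np.concatenate([[0], np.cumsum(nongap)])
        cs_match = np.concatenate([[0], np.cumsum(match & nongap)])
        for s in starts:
            e = s + window
            denom = cs_gap[e] - cs_gap[s]
            ident = (cs_match[e] - cs_match[s]) / denom if denom else np.nan
            rows.append((p.taxon_id, s, e, ident))
    return pd.DataFrame(rows, columns=["taxon_id", "start", "end", "identity"])
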