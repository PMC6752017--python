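"""Time- and control-corrected net increases of 16S relative abundance.

A taxon is scored as substrate-responsive by a three-step procedure applied
separately to the DNA (16S rRNA gene) and RNA (16S rRNA) strata:

1. relative abundances are averaged over replicates where the three
   replicates were sequenced separately and taken as single values where the
   replicates were pooled into one library;
2. the start-of-incubation abundance is subtracted from the end-of-incubation
   abundance, for the supplemented treatment and for the unsupplemented
   control (the time correction);
3. the control's time-corrected delta is subtracted from the treatment's,
   with negative control deltas ignored (treated as 0).

Nets are expressed in percentage points.  Families are screened at a >= 4
point net increase in at least one treatment, phylotypes at >= 2 points;
stimulated phylotypes whose representative sequences are >= 97% pairwise
identical are merged into group phylotypes (GPTs) by greedy seeded
clustering.  Alpha/beta diversity helpers (Shannon, Chao1, analytic
rarefaction, Bray-Curtis) cover the accompanying community summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "SampleMeta",
    "AbundanceTable",
    "NetIncreaseResult",
    "GroupPhylotype",
    "net_increase",
    "net_increase_matrix",
    "aggregate_by_rank",
    "screen_phylotypes",
    "pairwise_identity",
    "cluster_group_phylotypes",
    "shannon",
    "chao1",
    "rarefaction_curve",
    "bray_curtis",
]

T0, T_END = "t0", "t_end"
IUPAC_DNA = frozenset("ACGTURYSWKMBDHVN-")


@dataclass(frozen=True)
class SampleMeta:
    """Sequencing-sample metadata: treatment, time point, molecule, pooling."""

    treatment: str
    time: str  # "t0" | "t_end"
    molecule: str  # "DNA" | "RNA"
    replicate: int | None = None  # None = pooled single library

    def __post_init__(self) -> None:
        if self.time not in (T0, T_END):
            raise ValueError(f"time must be {T0!r} or {T_END!r}, got {self.time!r}")
        if self.molecule not in ("DNA", "RNA"):
            raise ValueError(f"molecule must be DNA or RNA, got {self.molecule!r}")
        if self.replicate is not None and self.replicate < 1:
            raise ValueError("replicate index must be >= 1 (None for pooled)")


class AbundanceTable:
    """Phylotype x sample relative abundances (fractions) with sample metadata.

    ``data`` is taxa (rows) x sample ids (columns); ``samples`` maps sample id
    to :class:`SampleMeta`; ``lineage`` optionally maps taxon id to a
    "phylum;family" string for rank aggregation.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        samples: Mapping[str, SampleMeta],
        lineage: Mapping[str, str] | pd.Series | None = None,
        validate: bool = True,
        tol: float = 1e-9,
    ) -> None:
        self.data = data.astype(float)
        self.samples = dict(samples)
        self.lineage = None if lineage is None else pd.Series(dict(lineage))
        missing = set(self.data.columns) - set(self.samples)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if validate:
            if (self.data.values < 0).any():
                raise ValueError("abundances must be non-negative")
            sums = self.data.sum(axis=0)
            bad = sums[(sums - 1.0).abs() > tol]
            if len(bad):
                raise ValueError(
                    f"sample abundances must sum to 1: {dict(bad.round(6))}"
                )

    def select(self, treatment: str, time: str, molecule: str) -> pd.DataFrame:
        cols = [
            s
            for s, m in self.samples.items()
            if m.treatment == treatment and m.time == time and m.molecule == molecule
        ]
        if not cols:
            raise KeyError(
                f"no sample for (treatment={treatment!r}, time={time!r}, "
                f"molecule={molecule!r})"
            )
        return self.data[cols]

    def mean_profile(self, treatment: str, time: str, molecule: str) -> pd.Series:
        """Replicate mean where replicated, single value where pooled."""
        return self.select(treatment, time, molecule).mean(axis=1)

    def rank_labels(self, rank: str) -> pd.Series:
        """Taxon -> rank label from "phylum;family" lineage strings.

        Unresolved ranks label as ``unclassified-<parent>``.
        """
        if self.lineage is None:
            raise ValueError("rank aggregation requires lineage strings")
        idx = {"phylum": 0, "family": 1}[rank]
        labels = {}
        for taxon in self.data.index:
            lin = self.lineage.get(taxon)
            parts = [] if not isinstance(lin, str) else lin.split(";")
            if len(parts) > idx and parts[idx]:
                labels[taxon] = parts[idx]
            else:
                parent = parts[idx - 1] if idx >= 1 and len(parts) >= idx else "root"
                labels[taxon] = f"unclassified-{parent}"
        return pd.Series(labels)

    def aggregate(self, rank: str) -> "AbundanceTable":
        """Sum abundances by lineage rank ('phylum' or 'family')."""
        grouped = self.data.groupby(self.rank_labels(rank)).sum()
        return AbundanceTable(grouped, self.samples, validate=False)


@dataclass
class NetIncreaseResult:
    """Per-taxon net increase (percentage points) for one treatment x molecule.

    ``signed`` retains the raw final subtraction for audit; the reported
    ``net`` clamps negatives at 0 as threshold screens require.
    ``delta_treatment`` / ``delta_control`` are the intermediate
    time-corrected deltas (percentage points).
    """

    treatment: str
    molecule: str
    signed: pd.Series
    delta_treatment: pd.Series
    delta_control: pd.Series

    @property
    def net(self) -> pd.Series:
        return self.signed.clip(lower=0.0)


def net_increase(
    table: AbundanceTable, treatment: str, control: str, molecule: str
) -> NetIncreaseResult:
    """Three-step net increase of relative abundance, in percentage points."""
    d_trt = table.mean_profile(treatment, T_END, molecule) - table.mean_profile(
        treatment, T0, molecule
    )
    d_ctl = table.mean_profile(control, T_END, molecule) - table.mean_profile(
        control, T0, molecule
    )
    signed = (d_trt - d_ctl.clip(lower=0.0)) * 100.0
    return NetIncreaseResult(
        treatment=treatment,
        molecule=molecule,
        signed=signed,
        delta_treatment=d_trt * 100.0,
        delta_control=d_ctl * 100.0,
    )


def net_increase_matrix(
    table: AbundanceTable,
    treatments: Sequence[str],
    control: str,
    molecules: Sequence[str] = ("DNA", "RNA"),
) -> pd.DataFrame:
    """Clamped nets for every treatment x molecule, taxa as rows."""
    cols = {}
    for trt in treatments:
        for mol in molecules:
            cols[(trt, mol)] = net_increase(table, trt, control, mol).net
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["treatment", "molecule"])
    return out


def aggregate_by_rank(
    table: AbundanceTable,
    rank: str,
    threshold: float,
    treatments: Sequence[str],
    control: str,
    molecules: Sequence[str] = ("DNA", "RNA"),
    order: str = "sum-first",
) -> pd.DataFrame:
    """Rank-level nets, keeping ranks with net >= threshold somewhere.

    ``order="sum-first"`` (default) sums abundances to the rank before the
    net-increase arithmetic; ``"sum-after"`` sums per-phylotype nets instead.
    """
    if order == "sum-first":
        nets = net_increase_matrix(table.aggregate(rank), treatments, control, molecules)
    elif order == "sum-after":
        per_taxon = net_increase_matrix(table, treatments, control, molecules)
        nets = per_taxon.groupby(table.rank_labels(rank)).sum()
    else:
        raise ValueError(f"unknown order {order!r}")
    keep = (nets >= threshold).any(axis=1)
    return nets[keep]


def screen_phylotypes(
    results: Iterable[NetIncreaseResult], threshold: float = 2.0
) -> list[str]:
    """Phylotypes with net >= threshold (points) in any supplemented stratum."""
    hits: set[str] = set()
    for res in results:
        hits.update(res.net[res.net >= threshold].index)
    return sorted(hits)


# ---------------------------------------------------------------------------
# Group-phylotype clustering


def _default_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    try:  # Biopython >= 1.88 names
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _validate_sequence(seq_id: str, seq: str) -> str:
    seq = str(seq).upper()
    bad = set(seq) - IUPAC_DNA
    if bad:
        raise ValueError(
            f"sequence {seq_id!r} contains non-IUPAC characters: {sorted(bad)}"
        )
    if not seq:
        raise ValueError(f"sequence {seq_id!r} is empty")
    return seq


def pairwise_identity(seq_a: str, seq_b: str, aligner=None) -> float:
    """Identity = matches / alignment length under end-gap-free global alignment.

    Terminal overhang columns are excluded; internal gap columns count in the
    denominator.
    """
    if aligner is None:
        aligner = _default_aligner()
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    s1, s2 = str(aln[0]), str(aln[1])
    start, end = 0, len(s1)
    while start < end and (s1[start] == "-" or s2[start] == "-"):
        start += 1
    while end > start and (s1[end - 1] == "-" or s2[end - 1] == "-"):
        end -= 1
    if end == start:
        return 0.0
    matches = sum(s1[i] == s2[i] and s1[i] != "-" for i in range(start, end))
    return matches / (end - start)


@dataclass
class GroupPhylotype:
    """Set of near-identical stimulated phylotypes treated as one unit."""

    representative: str
    members: list[str]
    identities: dict[str, float] = field(default_factory=dict)


def cluster_group_phylotypes(
    sequences: Mapping[str, str] | Iterable,
    net_by_id: Mapping[str, float] | None = None,
    identity_threshold: float = 0.97,
    aligner=None,
) -> list[GroupPhylotype]:
    """Greedy seeded clustering of representative sequences.

    Seeds are taken in order of descending maximal net increase (ties broken
    by lexicographic id; ids alone when no nets are given).  Each sequence
    joins the first existing seed with pairwise identity >= threshold,
    otherwise starts a new group; singletons remain ungrouped phylotypes.
    """
    if hasattr(sequences, "items"):
        records = {str(k): str(v) for k, v in sequences.items()}
    else:
        records = {}
        for rec in sequences:
            if hasattr(rec, "id") and hasattr(rec, "seq"):
                records[str(rec.id)] = str(rec.seq)
            else:
                seq_id, seq = rec
                records[str(seq_id)] = str(seq)
    if not records:
        raise ValueError("no sequences to cluster")
    records = {k: _validate_sequence(k, v) for k, v in records.items()}
    if aligner is None:
        aligner = _default_aligner()

    def sort_key(seq_id: str):
        score = net_by_id.get(seq_id, 0.0) if net_by_id else 0.0
        return (-score, seq_id)

    order = sorted(records, key=sort_key)
    groups: list[GroupPhylotype] = []
    for seq_id in order:
        placed = False
        for group in groups:
            ident = pairwise_identity(records[group.representative], records[seq_id], aligner)
            if ident >= identity_threshold:
                group.members.append(seq_id)
                group.identities[seq_id] = ident
                placed = True
                break
        if not placed:
            groups.append(
                GroupPhylotype(representative=seq_id, members=[seq_id],
                               identities={seq_id: 1.0})
            )
    return groups


# ---------------------------------------------------------------------------
# Diversity indices


def shannon(abundances, base: float | None = None) -> float:
    """Shannon diversity H = -sum p ln p (natural log unless ``base`` given)."""
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("abundances must not be all zero")
    p = p / total
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 expected richness from integer taxon counts.

    Bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) by default (defined even
    without doubletons); the classic F1^2/(2 F2) form is available by flag.
    """
    c = np.asarray(counts)
    if not np.all(np.equal(np.mod(c, 1), 0)) or (c < 0).any():
        raise ValueError("counts must be non-negative integers")
    c = c.astype(int)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0  # classic form's F2=0 fallback
    return s_obs + f1 * f1 / (2.0 * f2)


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Analytic expected richness E[S_d] under hypergeometric subsampling.

    E[S_d] = sum_i (1 - C(N - n_i, d) / C(N, d)), evaluated in log space.
    """
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    c = c[c > 0].astype(int)
    n_total = int(c.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=int))
    if (depths < 0).any() or (depths > n_total).any():
        raise ValueError(f"depths must lie in [0, {n_total}]")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = np.empty(len(depths), dtype=float)
    for j, d in enumerate(depths):
        with np.errstate(invalid="ignore"):
            log_p_absent = np.where(
                n_total - c >= d,
                log_choose(n_total - c, d) - log_choose(n_total, d),
                -np.inf,
            )
        out[j] = float((1.0 - np.exp(log_p_absent)).sum())
    return out


def bray_curtis(sample_a, sample_b) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum(min) / sum(a + b), in [0, 1]."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("both vectors are all zero")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / denom)
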