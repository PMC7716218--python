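"""Bulked-segregant SNP-index analysis.

Per-pool SNP-index (alt reads / total reads), delta SNP-index between the
phenotypically mutant and normal F2 bulks, a three-rule filter cascade that
strips mapping-parent (Ler) variants and keeps sites fixed for the alternate
allele in the mutant bulk, and a sliding-window profile used to localize the
causal region (the Manhattan-plot summary).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

# Pool identifiers for the five sequenced samples of the design.
PARENT_LINE = "PARENT_LINE"    # non-mutagenized reporter line (Col background)
ORIG_MUTANT = "ORIG_MUTANT"    # the isolated EMS mutant line
F2_MUTANT = "F2_MUTANT"        # bulk of phenotypically mutant F2 plants
F2_NORMAL = "F2_NORMAL"        # bulk of phenotypically normal F2 plants
LER_POOL = "LER"               # the mapping parent (Landsberg erecta)

ALL_POOLS = (PARENT_LINE, ORIG_MUTANT, F2_MUTANT, F2_NORMAL, LER_POOL)

# Filter statuses. REMOVED_PARENT is reachable only with use_line_pools=True.
RETAINED = "RETAINED"
REMOVED_LER = "REMOVED_LER"
REMOVED_F2NORMAL = "REMOVED_F2NORMAL"
REMOVED_F2MUTANT = "REMOVED_F2MUTANT"
REMOVED_LOW_DEPTH = "REMOVED_LOW_DEPTH"
REMOVED_PARENT = "REMOVED_PARENT"

REQUIRED_POOLS = (LER_POOL, F2_NORMAL, F2_MUTANT)


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic variant with per-pool allele depths.

    ``depths`` maps pool id -> (ref_depth, alt_depth).  A pool absent from
    the mapping was not sequenced at this site (absent != zero depth).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depths: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pool, (r, a) in self.depths.items():
            if r < 0 or a < 0:
                raise ValueError(f"negative depth for pool {pool} at {self.chrom}:{self.pos}")


@dataclass
class SnpIndexRecord:
    """A SnpRecord with per-pool SNP-indices and the bulk delta attached."""

    record: SnpRecord
    indices: dict[str, float | None]
    delta: float | None = None
    filter_status: str | None = None


def snp_index(ref_depth: int, alt_depth: int, min_depth: int = 5) -> float | None:
    """Alt-allele read fraction, or None when total depth < ``min_depth``."""
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("depths must be >= 0")
    total = ref_depth + alt_depth
    if total < min_depth:
        return None
    return alt_depth / total


def compute_indices(records: list[SnpRecord], min_depth: int = 5) -> list[SnpIndexRecord]:
    """Compute per-pool SNP-indices and the F2 mutant-minus-normal delta."""
    out = []
    for rec in records:
        idx = {
            pool: snp_index(r, a, min_depth=min_depth)
            for pool, (r, a) in rec.depths.items()
        }
        delta = None
        im, inorm = idx.get(F2_MUTANT), idx.get(F2_NORMAL)
        if im is not None and inorm is not None:
            delta = im - inorm
        out.append(SnpIndexRecord(rec, idx, delta))
    return out


def filter_cascade(
    records: list[SnpIndexRecord],
    *,
    epsilon: float = 0.0,
    use_line_pools: bool = False,
) -> list[SnpIndexRecord]:
    """Apply the variant filter cascade, setting ``filter_status`` on each record.

    Rules, in order:

    1. index undefined (low depth) in any required pool -> REMOVED_LOW_DEPTH;
    2. index > 0.5 in the Ler pool -> REMOVED_LER (mapping-parent variant);
    3. index > 0.5 in the F2 normal bulk -> REMOVED_F2NORMAL;
    4. index < 1 - epsilon in the F2 mutant bulk -> REMOVED_F2MUTANT
       (a causal recessive site must be fixed in the selected bulk);
    else RETAINED.

    With ``use_line_pools`` the site must additionally be fixed in the
    original mutant line and near-absent in the non-mutagenized parent line
    (REMOVED_PARENT otherwise); both 20X line pools are optional by default.
    """
    required = list(REQUIRED_POOLS)
    if use_line_pools:
        required += [PARENT_LINE, ORIG_MUTANT]
    out = []
    for rec in records:
        missing = [p for p in required if p not in rec.indices]
        if missing:
            raise ValueError(
                f"record {rec.record.chrom}:{rec.record.pos} lacks required "
                f"pool(s) {missing}"
            )
        out.append(replace_status(rec, epsilon=epsilon, use_line_pools=use_line_pools))
    return out


def replace_status(
    rec: SnpIndexRecord, *, epsilon: float = 0.0, use_line_pools: bool = False
) -> SnpIndexRecord:
    required = list(REQUIRED_POOLS)
    if use_line_pools:
        required += [PARENT_LINE, ORIG_MUTANT]
    idx = rec.indices
    if any(idx.get(p) is None for p in required):
        status = REMOVED_LOW_DEPTH
    elif idx[LER_POOL] > 0.5:
        status = REMOVED_LER
    elif idx[F2_NORMAL] > 0.5:
        status = REMOVED_F2NORMAL
    elif idx[F2_MUTANT] < 1.0 - epsilon:
        status = REMOVED_F2MUTANT
    elif use_line_pools and (
        idx[ORIG_MUTANT] < 1.0 - epsilon or idx[PARENT_LINE] > 0.5
    ):
        status = REMOVED_PARENT
    else:
        status = RETAINED
    return SnpIndexRecord(rec.record, dict(idx), rec.delta, status)


def retained(records: list[SnpIndexRecord]) -> list[SnpIndexRecord]:
    return [r for r in records if r.filter_status == RETAINED]


def delta_index_profile(
    records: list[SnpIndexRecord],
    window_size_bp: int = 1_000_000,
    step_bp: int = 200_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window mean delta SNP-index along each chromosome.

    Windows are half-open ``[start, start + window)`` on a 1-based axis,
    advancing by ``step_bp``.  Windows containing no SNP with a defined delta
    are reported with ``n_snps = 0`` and ``mean_delta = NaN`` (empty, not
    zero).  Output is sorted by chromosome then window start.
    """
    if not (window_size_bp >= step_bp > 0):
        raise ValueError("require window_size_bp >= step_bp > 0")
    per_chrom: dict[str, list[tuple[int, float]]] = {}
    for rec in records:
        if rec.delta is None:
            continue
        per_chrom.setdefault(rec.record.chrom, []).append((rec.record.pos, rec.delta))
    if chrom_lengths:
        for chrom in chrom_lengths:
            per_chrom.setdefault(chrom, [])
    rows = []
    for chrom in sorted(per_chrom):
        sites = sorted(per_chrom[chrom])
        if chrom_lengths and chrom in chrom_lengths:
            length = chrom_lengths[chrom]
        else:
            length = max((pos for pos, _ in sites), default=0)
        start = 1
        while True:
            end = start + window_size_bp  # half-open
            in_win = [d for pos, d in sites if start <= pos < end]
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_snps": len(in_win),
                    "mean_delta": (sum(in_win) / len(in_win)) if in_win else math.nan,
                }
            )
            start += step_bp
            if start > length:  # every bp up to `length` sits in some window
                break
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "mean_delta"])


@dataclass(frozen=True)
class PeakCall:
    chrom: str
    start: int
    end: int
    mean_delta: float
    tied: bool


def peak_support_region(profile: pd.DataFrame, frac: float = 0.5) -> tuple[str, int, int]:
    """Contiguous region of windows supporting the delta-index peak.

    On the peak chromosome, windows whose mean delta reaches ``frac`` of the
    peak mean are marked, and the contiguous run of marked windows containing
    the peak is merged into one (chrom, start, end) span — the usual way a
    bulked-segregant scan reports its candidate region rather than a single
    argmax window, which is noisy when SNPs are sparse.
    """
    peak = call_peak_region(profile)
    if peak.mean_delta <= 0:
        return peak.chrom, peak.start, peak.end - 1
    threshold = frac * peak.mean_delta
    rows = (
        profile[profile["chrom"] == peak.chrom]
        .sort_values("start")
        .reset_index(drop=True)
    )
    above = rows["mean_delta"].ge(threshold).fillna(False)
    peak_i = int(rows.index[rows["start"] == peak.start][0])
    lo = hi = peak_i
    while lo > 0 and above[lo - 1]:
        lo -= 1
    while hi < len(rows) - 1 and above[hi + 1]:
        hi += 1
    return peak.chrom, int(rows.loc[lo, "start"]), int(rows.loc[hi, "end"]) - 1


def call_peak_region(profile: pd.DataFrame) -> PeakCall:
    """Window of maximum mean delta; ties broken by chromosome then start."""
    nonempty = profile.dropna(subset=["mean_delta"])
    if nonempty.empty:
        raise ValueError("profile has no non-empty window")
    best = nonempty["mean_delta"].max()
    tied_rows = nonempty[nonempty["mean_delta"] == best].sort_values(["chrom", "start"])
    row = tied_rows.iloc[0]
    return PeakCall(
        chrom=str(row["chrom"]),
        start=int(row["start"]),
        end=int(row["end"]),
        mean_delta=float(best),
        tied=len(tied_rows) > 1,
    )
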