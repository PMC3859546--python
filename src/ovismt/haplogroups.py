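"""Haplogroup classification and tandem-repeat cluster assignment.

Two independent markers assign sheep mtDNA lineages:

1. Diagnostic control-region sites. Five positions on AF010406 (15459,
   15476, 15484, 15509, 15512) carry derived bases that separate the
   domestic haplogroups: HPG A = T@15459 + A@15484, HPG C = G@15509,
   HPG E = C@15476 + G@15509; HPG B is the reference haplogroup (the
   reference base at every diagnostic site). A sample is called for a
   non-reference haplogroup when it carries ALL of that haplogroup's
   derived bases; additional private variants at other diagnostic sites
   do not block the call (ancient samples do carry such variants). A
   sample completing no signature — or more than one — is unassigned:
   partial matches are never resolved to the nearest haplogroup, because
   ancient-DNA damage makes nearest-match calling unsafe.

2. Tandem-repeat unit length. The CR carries 3-5 tandem copies of a
   ~75-bp unit starting near position 15640. The first unit is always
   75 bp; the length of the following units is 75 bp in cluster i
   (HPGs A, B, D) and 76 bp in cluster ii (HPGs C, E and the wild
   anatolica X haplotype).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import DIAGNOSTIC_RULES
from .seqio import AlignedSeq

__all__ = [
    "DiagnosticTable",
    "HaplogroupCall",
    "RepeatProfile",
    "default_diagnostic_table",
    "classify",
    "classify_observed",
    "classify_genotype_table",
    "parse_repeats",
    "frequency_table",
    "stratify_by_era",
]

MISSING_BASES = frozenset("N-")
REF_SENTINEL = "."  # published-table notation for "same as reference"


@dataclasses.dataclass
class DiagnosticTable:
    """Diagnostic-site scheme: derived bases per haplogroup.

    rules maps haplogroup -> {position: derived base}; the reference
    haplogroup has an empty rule and matches when every diagnostic site
    carries the reference base. Haplogroups with no signature and not the
    reference (e.g. HPG D in the shipped five-site scheme) can never be
    called. User extensions simply add positions/rules.
    """

    rules: Mapping[str, Mapping[int, str]]
    reference_haplogroup: str = "B"

    def __post_init__(self) -> None:
        sigs = {}
        for name, rule in self.rules.items():
            if not rule and name != self.reference_haplogroup:
                continue  # unassignable placeholder (no published signature)
            key = tuple(sorted(rule.items()))
            if key in sigs:
                raise ValueError(
                    f"haplogroups {sigs[key]!r} and {name!r} share a signature"
                )
            sigs[key] = name

    @property
    def positions(self) -> tuple[int, ...]:
        pos = set()
        for rule in self.rules.values():
            pos.update(rule)
        return tuple(sorted(pos))


@dataclasses.dataclass
class HaplogroupCall:
    sample_id: str
    haplogroup: str  # A|B|C|D|E|X|unassigned
    observed_bases: dict[int, str]
    n_missing: int = 0


@dataclasses.dataclass
class RepeatProfile:
    """Ordered tandem-repeat unit lengths and the cluster they imply."""

    unit_lengths: list[int]
    cluster: str = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        later = self.unit_lengths[1:]
        if later and all(u == 75 for u in later):
            self.cluster = "i"
        elif later and all(u == 76 for u in later):
            self.cluster = "ii"
        else:
            self.cluster = "undetermined"

    @property
    def n_units(self) -> int:
        return len(self.unit_lengths)


def default_diagnostic_table(
    extra_rules: Mapping[str, Mapping[int, str]] | None = None,
) -> DiagnosticTable:
    """The shipped five-site scheme, optionally extended with user rules."""
    rules = {k: dict(v) for k, v in DIAGNOSTIC_RULES.items()}
    for name, rule in (extra_rules or {}).items():
        rules.setdefault(name, {}).update(rule)
    return DiagnosticTable(rules)


def classify_observed(
    sample_id: str,
    observed: Mapping[int, str],
    table: DiagnosticTable,
    reference_bases: Mapping[int, str] | None = None,
    max_missing: int = 0,
) -> HaplogroupCall:
    """Classify from observed bases at diagnostic positions.

    `observed` maps position -> base, '.' (reference), or a missing symbol
    (N/-); positions absent from the map count as missing. When bases are
    given literally (not dot-notation), `reference_bases` must supply the
    reference base at each diagnostic position so "equals reference" is
    decidable.
    """
    positions = table.positions
    obs: dict[int, str] = {}
    n_missing = 0
    for pos in positions:
        b = observed.get(pos)
        if b is None or b.upper() in MISSING_BASES:
            n_missing += 1
            continue
        obs[pos] = b.upper() if b != REF_SENTINEL else REF_SENTINEL
    if n_missing > max_missing:
        return HaplogroupCall(sample_id, "unassigned", obs, n_missing)

    def is_ref(pos: int) -> bool:
        b = obs[pos]
        if b == REF_SENTINEL:
            return True
        if reference_bases is None or pos not in reference_bases:
            # dot-notation input spells reference bases as '.'; a literal
            # base is a variant by construction
            return False
        return b == reference_bases[pos].upper()

    def equals(pos: int, base: str) -> bool:
        b = obs[pos]
        if b == REF_SENTINEL:
            return reference_bases is not None and reference_bases.get(
                pos, ""
            ).upper() == base.upper()
        return b == base.upper()

    matches = []
    for name, rule in table.rules.items():
        if not rule:
            continue
        if all(pos in obs and equals(pos, base) for pos, base in rule.items()):
            matches.append(name)
    if len(matches) > 1:
        # most-specific rule wins: drop any match whose signature positions
        # are a strict subset of another match's (HPG C's G@15509 is subsumed
        # by HPG E's C@15476+G@15509)
        possets = {m: set(table.rules[m]) for m in matches}
        matches = [
            m
            for m in matches
            if not any(
                possets[m] < possets[o] for o in matches if o != m
            )
        ]
    if len(matches) == 1:
        return HaplogroupCall(sample_id, matches[0], obs, n_missing)
    if len(matches) == 0 and all(is_ref(p) for p in obs):
        return HaplogroupCall(sample_id, table.reference_haplogroup, obs, n_missing)
    return HaplogroupCall(sample_id, "unassigned", obs, n_missing)


def classify(
    seq: AlignedSeq,
    table: DiagnosticTable,
    reference: AlignedSeq,
    max_missing: int = 0,
) -> HaplogroupCall:
    """Classify an anchored sequence against an anchored reference."""
    observed: dict[int, str] = {}
    ref_bases: dict[int, str] = {}
    for pos in table.positions:
        rb = reference.base_at(pos)
        if rb is not None:
            ref_bases[pos] = rb
        b = seq.base_at(pos)
        if b is not None:
            observed[pos] = b
    return classify_observed(seq.id, observed, table, ref_bases, max_missing)


def classify_genotype_table(
    genotypes: pd.DataFrame,
    table: DiagnosticTable | None = None,
    max_missing: int = 0,
) -> list[HaplogroupCall]:
    """Classify a published-style genotype table (dot = reference base).

    Expects an 'id' column and one 'p<position>' column per diagnostic
    position.
    """
    table = table or default_diagnostic_table()
    calls = []
    for _, row in genotypes.iterrows():
        observed = {
            pos: str(row[f"p{pos}"]) for pos in table.positions if f"p{pos}" in row
        }
        calls.append(
            classify_observed(str(row["id"]), observed, table, None, max_missing)
        )
    return calls


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def _best_76_match(cand: np.ndarray, motif: np.ndarray) -> int:
    """Min mismatches of a 76-mer vs the 75-bp motif over one deletion."""
    best = len(motif)
    for g in range(cand.size):
        d = _hamming(np.delete(cand, g), motif)
        if d < best:
            best = d
    return best


def parse_repeats(
    seq: AlignedSeq,
    motif_seed: str | None = None,
    expected_start: int = 15640,
    window: int = 30,
    d_max: int = 5,
) -> RepeatProfile:
    """Locate and measure the CR tandem-repeat units.

    The first 75-bp unit is found near `expected_start` (within ±window bp)
    either by matching `motif_seed` (a prefix of the unit) or, without a
    seed, by self-similarity: the offset whose next 75-mer best matches the
    75-mer that follows it. Subsequent units are matched greedily against
    the first unit, each allowed to be 75 or 76 bp with at most d_max
    internal mismatches. Unit counts outside 3-5 draw a warning.
    """
    res = np.frombuffer(seq.record.residues.encode(), dtype=np.uint8)
    if not seq.coords.covers(expected_start):
        raise ValueError("repeat region not found: expected start unmapped")
    c0 = seq.coords.ref_to_column(expected_start)
    lo = max(0, c0 - window)
    hi = min(res.size - 2 * 75, c0 + window)
    start = None
    if motif_seed:
        m = np.frombuffer(motif_seed.upper().encode(), dtype=np.uint8)
        for p in range(lo, hi + 1):
            if p + m.size <= res.size and _hamming(res[p : p + m.size], m) <= max(
                1, m.size // 10
            ):
                start = p
                break
    else:
        best = None
        for p in range(lo, hi + 1):
            first = res[p : p + 75]
            # next unit may be 75 or 76 bp (cluster ii inserts one base)
            d75 = _hamming(first, res[p + 75 : p + 150])
            d76 = (
                _best_76_match(res[p + 75 : p + 151], first)
                if p + 151 <= res.size
                else 10**9
            )
            d = min(d75, d76)
            if best is None or d < best[0]:
                best = (d, p)
        if best is not None and best[0] <= d_max:
            start = best[1]
    if start is None:
        raise ValueError("repeat region not found")

    motif = res[start : start + 75]
    lengths = [75]
    p = start + 75
    while True:
        cand75 = res[p : p + 75]
        d75 = _hamming(cand75, motif) if cand75.size == 75 else 10**9
        d76 = (
            _best_76_match(res[p : p + 76], motif)
            if p + 76 <= res.size
            else 10**9
        )
        if d75 <= d76 and d75 <= d_max:
            lengths.append(75)
            p += 75
        elif d76 < d75 and d76 <= d_max:
            lengths.append(76)
            p += 76
        else:
            break
    if not 3 <= len(lengths) <= 5:
        warnings.warn(
            f"{seq.id}: {len(lengths)} repeat units (expected 3-5)", stacklevel=2
        )
    return RepeatProfile(lengths)


def frequency_table(
    calls: Sequence[HaplogroupCall],
    strata: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Counts and percentages per haplogroup, optionally per stratum.

    `strata` maps sample_id -> stratum label; unmapped samples go to
    "all". Percentages are over assigned+unassigned calls of the stratum.
    """
    if not calls:
        raise ValueError("no calls to tabulate")
    rows = [
        {
            "stratum": (strata or {}).get(c.sample_id, "all"),
            "haplogroup": c.haplogroup,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows)
    out = []
    for stratum, grp in df.groupby("stratum"):
        n = len(grp)
        for hpg, cnt in grp["haplogroup"].value_counts().items():
            out.append(
                {
                    "stratum": stratum,
                    "haplogroup": hpg,
                    "count": int(cnt),
                    "n": n,
                    "percent": round(100.0 * cnt / n, 1),
                }
            )
    return (
        pd.DataFrame(out)
        .sort_values(["stratum", "haplogroup"])
        .reset_index(drop=True)
    )


def stratify_by_era(
    genotypes: pd.DataFrame, strata: Sequence[tuple[int, int]]
) -> dict[str, str]:
    """Assign samples to BCE era strata by date-interval containment.

    A sample with archaeological date [date_early, date_late] BCE joins
    stratum (a, b) iff a >= date_early >= date_late >= b. Samples fitting
    no stratum are left out of the mapping.
    """
    mapping: dict[str, str] = {}
    for _, row in genotypes.iterrows():
        for a, b in strata:
            if a >= row["date_early"] >= row["date_late"] >= b:
                mapping[str(row["id"])] = f"{a}-{b} BCE"
                break
    return mapping
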