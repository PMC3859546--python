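"""Synthetic data generators.

The generators emulate the statistical structure of sheep mtDNA survey
data so every downstream stage is testable offline:

* a control-region panel whose sequences carry haplogroup-diagnostic bases
  at the five classifier positions, a tandem-repeat region whose
  second-and-later unit length (75 vs 76 bp) tracks the two haplogroup
  clusters (A/B/D vs C/E/X), and Poisson private mutations;
* coalescent samples under constant-size and sudden-expansion
  demographies (see `ovismt.coalescent` for the time scale);
* flocks on a plane with a longitudinal haplogroup-frequency cline.

All generators are pure functions of (parameters, seed). The reference
sequence used by the panel generator is SYNTHETIC: a fixed pseudo-random
stand-in for the real AF010406 control region that reproduces its
coordinate layout (CR at 15437–16616, diagnostic sites, a 75-bp repeat
unit starting at position 15640) but not its actual bases.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import coalescent as _coal
from .datasets import DIAGNOSTIC_RULES
from .seqio import SeqRecord

__all__ = [
    "HaplogroupSpec",
    "ClineSpec",
    "synthetic_reference",
    "default_panel_specs",
    "gen_haplogroup_panel",
    "gen_coalescent",
    "gen_spatial_panel",
    "REF_START",
    "REPEAT_START",
    "REPEAT_UNIT_LEN",
]

# Coordinate layout mirroring the real sequence: the synthetic reference
# spans the partial tRNA-Pro + control region (15391..16616) so both the
# ancient 144-bp window (15391-15534) and the full CR (15437-16616) are
# addressable.
REF_START = 15391
REF_END = 16616
REPEAT_START = 15640       # reference position of the first repeat unit
REPEAT_UNIT_LEN = 75       # the first unit is always 75 bp
_N_REF_UNITS = 4           # modal unit count
_UNIT_COUNT_PROBS = {3: 0.07, 4: 0.92, 5: 0.01}
_ANCIENT_WINDOW = (15391, 15534)  # diagnostic scheme must sit inside this

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Reference bases at the diagnostic positions (synthetic choice,
#: constrained to differ from every published derived base at each site).
#: 15466 is pinned so the synthetic wild-X extension rule (15466->T) is
#: guaranteed distinct from the reference.
SYNTHETIC_REF_DIAGNOSTIC = {
    15459: "C",
    15466: "A",
    15476: "A",
    15484: "G",
    15509: "C",
    15512: "A",
}


@dataclasses.dataclass
class HaplogroupSpec:
    """What the panel generator needs to emit one haplogroup.

    diagnostic_bases maps reference position -> derived base (empty only
    for the reference haplogroup); repeat_unit_length is the length (75 or
    76) of the second and subsequent repeat units; base_frequency is the
    haplogroup's proportion in a simulated population.
    """

    name: str
    diagnostic_bases: dict[int, str]
    repeat_unit_length: int
    base_frequency: float

    def __post_init__(self) -> None:
        if self.repeat_unit_length not in (75, 76):
            raise ValueError("repeat_unit_length must be 75 or 76")
        for pos in self.diagnostic_bases:
            if not (_ANCIENT_WINDOW[0] <= pos <= _ANCIENT_WINDOW[1]):
                raise ValueError(
                    f"diagnostic position {pos} outside the ancient-fragment "
                    f"window {_ANCIENT_WINDOW}"
                )
        if self.base_frequency < 0:
            raise ValueError("base_frequency must be >= 0")


@dataclasses.dataclass
class ClineSpec:
    """Linear west->east frequency gradient for one focal haplogroup."""

    haplogroup: str = "B"
    west_freq: float = 0.6
    east_freq: float = 0.2


def _ref_rng() -> np.random.Generator:
    # fixed stream: the synthetic reference is a constant of the package
    return np.random.default_rng(np.random.SeedSequence(20130081952))


def synthetic_reference() -> SeqRecord:
    """The fixed synthetic CR reference (positions 15437..16616).

    Prefix 15391..15639, then four identical 75-bp repeat units, then a
    random tail; diagnostic sites carry SYNTHETIC_REF_DIAGNOSTIC bases.
    """
    rng = _ref_rng()
    prefix_len = REPEAT_START - REF_START          # 249
    prefix = rng.choice(_BASES, size=prefix_len)
    for pos, base in SYNTHETIC_REF_DIAGNOSTIC.items():
        prefix[pos - REF_START] = ord(base)
    unit = rng.choice(_BASES, size=REPEAT_UNIT_LEN)  # same stream position
    rep = np.concatenate([unit] * _N_REF_UNITS)      # as repeat_unit_75()
    tail_len = (REF_END - REF_START + 1) - prefix_len - rep.size
    tail = rng.choice(_BASES, size=tail_len)
    seq = bytes(np.concatenate([prefix, rep, tail])).decode()
    return SeqRecord("SYN_REF_CR", seq, {"synthetic": True})


def repeat_unit_75() -> np.ndarray:
    """The synthetic 75-bp repeat unit (uint8 array)."""
    rng = _ref_rng()
    rng.choice(_BASES, size=REPEAT_START - REF_START)  # skip prefix stream
    return rng.choice(_BASES, size=REPEAT_UNIT_LEN)


def repeat_unit_76() -> np.ndarray:
    """The 76-bp variant: one base inserted mid-unit (cluster-ii marker)."""
    u = repeat_unit_75()
    ins_at = 38
    return np.concatenate([u[:ins_at], np.array([ord("T")], dtype=np.uint8), u[ins_at:]])


def default_panel_specs(include_wild_x: bool = False) -> list[HaplogroupSpec]:
    """Domestic haplogroup specs with published diagnostic bases.

    Frequencies follow the sequenced modern domestic panel (A:70, B:88,
    C:69, E:11 of 238 classifiable); HPG D is omitted by default because
    the five-site scheme gives it no signature. With include_wild_x, a
    wild-X spec with a SYNTHETIC extension signature (15466->T) is added
    so cluster-consistency can be exercised end to end.
    """
    freqs = {"A": 70, "B": 88, "C": 69, "E": 11}
    tot = sum(freqs.values())
    specs = [
        HaplogroupSpec("A", dict(DIAGNOSTIC_RULES["A"]), 75, freqs["A"] / tot),
        HaplogroupSpec("B", dict(DIAGNOSTIC_RULES["B"]), 75, freqs["B"] / tot),
        HaplogroupSpec("C", dict(DIAGNOSTIC_RULES["C"]), 76, freqs["C"] / tot),
        HaplogroupSpec("E", dict(DIAGNOSTIC_RULES["E"]), 76, freqs["E"] / tot),
    ]
    if include_wild_x:
        for s in specs:
            s.base_frequency *= 0.9
        specs.append(HaplogroupSpec("X", {15466: "T"}, 76, 0.1))
    return specs


def _signature_key(spec: HaplogroupSpec) -> tuple:
    return tuple(sorted(spec.diagnostic_bases.items()))


def gen_haplogroup_panel(
    specs: Sequence[HaplogroupSpec],
    n: int,
    private_mut_rate: float = 1.0,
    seed: int = 0,
) -> list[SeqRecord]:
    """Simulate n CR sequences drawn from the given haplogroup specs.

    Each sequence is the synthetic reference with its spec's diagnostic
    bases applied, a first 75-bp repeat unit followed by 2-4 further units
    of the spec's length (unit counts 3-5, mode 4), and Poisson private
    substitutions at non-diagnostic positions. The true label is stored in
    meta["true_hpg"]; meta["n_units"] records the simulated unit count.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sigs = [_signature_key(s) for s in specs]
    if len(set(sigs)) != len(sigs):
        raise ValueError("two specs share an identical diagnostic signature")
    rng = np.random.default_rng(seed)
    ref = synthetic_reference()
    prefix = np.frombuffer(ref.residues.encode(), dtype=np.uint8)[
        : REPEAT_START - REF_START
    ].copy()
    tail_start = (REPEAT_START - REF_START) + _N_REF_UNITS * REPEAT_UNIT_LEN
    tail = np.frombuffer(ref.residues.encode(), dtype=np.uint8)[tail_start:]
    u75, u76 = repeat_unit_75(), repeat_unit_76()

    probs = np.array([s.base_frequency for s in specs], dtype=float)
    probs = probs / probs.sum()
    counts = list(_UNIT_COUNT_PROBS)
    cprobs = np.array([_UNIT_COUNT_PROBS[c] for c in counts])
    diag_cols = {
        pos - REF_START
        for s in specs
        for pos in s.diagnostic_bases
    } | {pos - REF_START for pos in SYNTHETIC_REF_DIAGNOSTIC}

    out: list[SeqRecord] = []
    for i in range(n):
        spec = specs[rng.choice(len(specs), p=probs)]
        pre = prefix.copy()
        for pos, base in spec.diagnostic_bases.items():
            pre[pos - REF_START] = ord(base)
        n_units = int(counts[rng.choice(len(counts), p=cprobs)])
        later = u75 if spec.repeat_unit_length == 75 else u76
        seq = np.concatenate([pre, u75] + [later] * (n_units - 1) + [tail])
        # private mutations avoid diagnostic sites (they live in the prefix)
        n_mut = rng.poisson(private_mut_rate)
        for _ in range(n_mut):
            while True:
                col = int(rng.integers(seq.size))
                if col not in diag_cols:
                    break
            seq[col] = rng.choice(_BASES[_BASES != seq[col]])
        out.append(
            SeqRecord(
                f"SYN{i:04d}",
                bytes(seq).decode(),
                {"true_hpg": spec.name, "n_units": n_units, "synthetic": True},
            )
        )
    return out


def gen_coalescent(
    dem: _coal.DemographySpec, seed: int = 0, ancestral: str | None = None
) -> list[SeqRecord]:
    """Simulate one infinite-sites coalescent sample as SeqRecords.

    Supplying the same `ancestral` sequence to several calls places the
    groups on a common background (their Dxy then reflects only the
    accumulated polymorphism, not random ancestral differences).
    """
    if dem.n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    gen = _coal.drop_mutations(_coal.sim_genealogy(dem, rng), rng)
    seqs = _coal.genealogy_sequences(gen, rng, dem.L, ancestral=ancestral)
    return [
        SeqRecord(f"COAL{i:04d}", s, {"synthetic": True}) for i, s in enumerate(seqs)
    ]


def gen_spatial_panel(
    n_flocks: int,
    flock_size: int,
    cline: ClineSpec | None = None,
    extent_km: float = 1500.0,
    specs: Sequence[HaplogroupSpec] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Flocks on a plane with a location-dependent haplogroup mix.

    Returns a DataFrame (id, flock, x_km, y_km, haplogroup). The focal
    haplogroup's frequency varies linearly from cline.west_freq at x=0 to
    cline.east_freq at x=extent_km; the other haplogroups share the
    remaining mass in proportion to their base frequencies. cline=None
    means no gradient (base frequencies everywhere). Individuals of a
    flock share the flock's coordinates, mirroring flock-level sampling.
    """
    if n_flocks < 2:
        raise ValueError("need at least two flocks")
    if extent_km <= 0:
        raise ValueError("degenerate map extent")
    specs = list(specs) if specs is not None else default_panel_specs()
    names = [s.name for s in specs]
    base = np.array([s.base_frequency for s in specs], dtype=float)
    base = base / base.sum()
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0.0, extent_km, size=(n_flocks, 2))
    rows = []
    for f in range(n_flocks):
        x = xy[f, 0]
        p = base.copy()
        if cline is not None:
            fi = names.index(cline.haplogroup)
            w = x / extent_km
            focal = (1 - w) * cline.west_freq + w * cline.east_freq
            rest = np.delete(p, fi)
            rest = rest / rest.sum() * (1 - focal)
            p = np.insert(rest, fi, focal)
        for j in range(flock_size):
            hpg = names[rng.choice(len(names), p=p)]
            rows.append(
                {
                    "id": f"F{f:03d}-{j:03d}",
                    "flock": f"F{f:03d}",
                    "x_km": xy[f, 0],
                    "y_km": xy[f, 1],
                    "haplogroup": hpg,
                }
            )
    return pd.DataFrame(rows)
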