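"""End-to-end orchestration: one config, deterministic seeding, reports.

A RunConfig (typically loaded from YAML) names the inputs and the stages
to run (classify, diversity, neutrality, mismatch, spatial, tree,
network). Each stage writes a TSV/JSON report into the output directory
and a manifest records inputs, parameters and the seeds actually used,
so any report can be reproduced exactly.

Seeding: one master seed; stage i uses (master * 1000003 + i) mod 2^31,
a fixed counter scheme so a stage's stream does not depend on which
other stages are enabled.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import diversity as _div
from . import haplogroups as _hap
from . import mismatch as _mm
from . import neutrality as _neu
from . import phylo as _phylo
from . import spatial as _spatial
from . import synthetic as _syn
from .datasets import oylum_ancient_genotypes
from .network import mj_network
from .seqio import read_fasta, write_fasta

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "stage_seed"]

_STAGE_ORDER = (
    "classify",
    "diversity",
    "neutrality",
    "mismatch",
    "spatial",
    "tree",
    "network",
)


def stage_seed(master: int, stage: str) -> int:
    return (int(master) * 1000003 + _STAGE_ORDER.index(stage)) % (2**31)


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: str
    seed: int = 0
    stages: list[str] = dataclasses.field(default_factory=list)
    inputs: dict[str, str] = dataclasses.field(default_factory=dict)
    params: dict[str, dict[str, Any]] = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            out_dir=raw["out_dir"],
            seed=int(raw.get("seed", 0)),
            stages=list(raw.get("stages", [])),
            inputs={k: str(v) for k, v in raw.get("inputs", {}).items()},
            params=raw.get("params", {}),
        )

    def validate(self) -> None:
        for s in self.stages:
            if s not in _STAGE_ORDER:
                raise ValueError(f"unknown stage {s!r}")
        needs = {
            "classify": ["genotypes"],
            "diversity": ["alignment"],
            "neutrality": ["alignment"],
            "mismatch": ["alignment"],
            "spatial": ["spatial_table"],
            "tree": ["alignment"],
            "network": ["alignment"],
        }
        for s in self.stages:
            for key in needs[s]:
                if key not in self.inputs:
                    raise ValueError(f"stage {s!r} requires input {key!r}")
                p = Path(self.inputs[key])
                if not p.exists():
                    raise FileNotFoundError(f"input {key!r}: {p} does not exist")


def _stage_classify(cfg: RunConfig, out: Path) -> dict:
    geno = pd.read_csv(cfg.inputs["genotypes"], sep="\t", dtype={"id": str})
    calls = _hap.classify_genotype_table(geno)
    df = pd.DataFrame(
        {
            "id": [c.sample_id for c in calls],
            "haplogroup": [c.haplogroup for c in calls],
            "evidence": [
                ";".join(f"{p}{b}" for p, b in sorted(c.observed_bases.items()))
                for c in calls
            ],
            "n_missing": [c.n_missing for c in calls],
        }
    )
    df.to_csv(out / "haplogroups.tsv", sep="\t", index=False)
    _hap.frequency_table(calls).to_csv(
        out / "haplogroup_frequencies.tsv", sep="\t", index=False
    )
    return {"n_samples": len(calls)}


def _load_alignment(cfg: RunConfig):
    return read_fasta(cfg.inputs["alignment"])


def _stage_diversity(cfg: RunConfig, out: Path) -> dict:
    seqs = _load_alignment(cfg)
    st = _div.diversity_stats(seqs)
    pd.DataFrame(
        [
            {
                "n": st.n,
                "n_haplotypes": st.k,
                "h": round(st.h, 4),
                "h_sd": round(st.h_sd, 4),
                "pi": st.pi,
                "pi_sd": st.pi_sd,
            }
        ]
    ).to_csv(out / "diversity.tsv", sep="\t", index=False)
    return {"n": st.n, "k": st.k}


def _stage_neutrality(cfg: RunConfig, out: Path) -> dict:
    seqs = _load_alignment(cfg)
    p = cfg.params.get("neutrality", {})
    reps = int(p.get("n_reps", 10_000))
    seed = stage_seed(cfg.seed, "neutrality")
    d = _neu.tajimas_d(seqs, n_reps=reps, seed=seed)
    fs = _neu.fus_fs(seqs, n_reps=reps, seed=seed + 1)
    pd.DataFrame(
        [
            {"statistic": r.statistic_name, "value": r.value, "p": r.p_value,
             "n": r.n, "S": r.S, "theta_pi": r.theta_pi}
            for r in (d, fs)
        ]
    ).to_csv(out / "neutrality.tsv", sep="\t", index=False)
    return {"D": d.value, "Fs": fs.value}


def _stage_mismatch(cfg: RunConfig, out: Path) -> dict:
    seqs = _load_alignment(cfg)
    p = cfg.params.get("mismatch", {})
    obs = _mm.observed_mismatch(seqs)
    fit = _mm.fit_expansion(obs)
    n_boot = int(p.get("n_boot", 1000))
    fit.p_ssd = _mm.ssd_test(
        obs, fit, n_boot=n_boot, seed=stage_seed(cfg.seed, "mismatch")
    )
    fit.n_boot = n_boot
    pd.DataFrame(
        {"j": np.arange(obs.freqs.size), "observed": obs.freqs,
         "expected": _mm.expected_mismatch(fit.tau, max(fit.theta0, 1e-9),
                                           fit.theta1, obs.freqs.size - 1)}
    ).to_csv(out / "mismatch_distribution.tsv", sep="\t", index=False)
    with open(out / "mismatch_fit.json", "w") as fh:
        json.dump(dataclasses.asdict(fit), fh, indent=2)
    return {"tau": fit.tau, "p_ssd": fit.p_ssd}


def _stage_spatial(cfg: RunConfig, out: Path) -> dict:
    tab = pd.read_csv(cfg.inputs["spatial_table"], sep="\t")
    p = cfg.params.get("spatial", {})
    if {"x_km", "y_km"}.issubset(tab.columns):
        coords = tab[["x_km", "y_km"]].to_numpy()
        metric = "planar"
    else:
        coords = tab[["lat", "lon"]].to_numpy()
        metric = "great_circle"
    keep = tab["haplogroup"] != "unassigned"
    spec = _spatial.DistanceClassSpec(
        class_width_km=float(p.get("class_width_km", 150.0)),
        n_classes=int(p.get("n_classes", 14)),
        metric=metric,
    )
    res = _spatial.autocorrelogram(
        _spatial.genetic_distance_matrix(tab.loc[keep, "haplogroup"].tolist()),
        coords[keep.to_numpy()],
        spec,
        n_perm=int(p.get("n_perm", 999)),
        n_boot=int(p.get("n_boot", 1000)),
        seed=stage_seed(cfg.seed, "spatial"),
    )
    res.to_frame().to_csv(out / "correlogram.tsv", sep="\t", index=False)
    return {"n_classes": spec.n_classes}


def _stage_tree(cfg: RunConfig, out: Path) -> dict:
    seqs = _load_alignment(cfg)
    p = cfg.params.get("tree", {})
    dm = _phylo.tn93_matrix(seqs)
    tree = _phylo.nj_tree(dm)
    support = _phylo.bootstrap_support(
        seqs, n_reps=int(p.get("n_reps", 1000)), seed=stage_seed(cfg.seed, "tree")
    )
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        taxa = frozenset(t.name for t in tree.tips())
        anchor = min(taxa)
        canonical = side if anchor in side else taxa - side
        if canonical in support:
            node.name = f"{support[canonical]:.0f}"
    tree.write(str(out / "nj_tree.nwk"))
    return {"n_taxa": len(dm.ids)}


def _stage_network(cfg: RunConfig, out: Path) -> dict:
    seqs = _load_alignment(cfg)
    tab = _div.collapse_haplotypes(seqs)
    net = mj_network(tab.haplotypes, tab.counts)
    rows = [
        {"a": u, "b": v, "n_mut": d["n_mut"],
         "positions": ",".join(map(str, d["positions"]))}
        for u, v, d in net.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(out / "network_edges.tsv", sep="\t", index=False)
    return {"n_nodes": net.number_of_nodes(), "n_edges": net.number_of_edges()}


_STAGE_FN = {
    "classify": _stage_classify,
    "diversity": _stage_diversity,
    "neutrality": _stage_neutrality,
    "mismatch": _stage_mismatch,
    "spatial": _stage_spatial,
    "tree": _stage_tree,
    "network": _stage_network,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all enabled stages; returns the manifest (also written to disk).

    A stage failure is recorded with a FAILED marker and re-raised after
    the manifest is flushed, so partial outputs remain inspectable.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": cfg.seed,
        "inputs": cfg.inputs,
        "params": cfg.params,
        "stages": {},
    }
    failure: Exception | None = None
    for stage in _STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        try:
            info = _STAGE_FN[stage](cfg, out)
            manifest["stages"][stage] = {
                "status": "ok",
                "seed": stage_seed(cfg.seed, stage),
                **info,
            }
        except Exception as exc:  # noqa: BLE001 - recorded then re-raised
            manifest["stages"][stage] = {"status": "FAILED", "error": str(exc)}
            failure = exc
            break
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    if failure is not None:
        raise failure
    return manifest


def make_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write the packaged test inputs; idempotent for a given seed.

    Produces the published ancient genotype table, a small synthetic CR
    panel (FASTA + metadata TSV), and a synthetic spatial table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    geno = oylum_ancient_genotypes()
    paths["genotypes"] = out / "ancient_genotypes.tsv"
    geno.to_csv(paths["genotypes"], sep="\t", index=False)

    panel = _syn.gen_haplogroup_panel(
        _syn.default_panel_specs(), n=40, private_mut_rate=1.0, seed=seed
    )
    paths["panel_fasta"] = out / "synthetic_panel.fasta"
    write_fasta(panel, paths["panel_fasta"])

    # equal-length alignment: the pre-repeat CR segment (repeat-unit count
    # varies between individuals, so downstream alignment stages use the
    # fragment upstream of the tandem repeat)
    from .seqio import SeqRecord as _SR

    pre_len = _syn.REPEAT_START - _syn.REF_START
    aln = [_SR(r.id, r.residues[:pre_len], dict(r.meta)) for r in panel]
    paths["alignment"] = out / "synthetic_alignment.fasta"
    write_fasta(aln, paths["alignment"])
    meta = pd.DataFrame(
        {"id": [r.id for r in panel], "group": [r.meta["true_hpg"] for r in panel]}
    )
    paths["panel_meta"] = out / "synthetic_panel_meta.tsv"
    meta.to_csv(paths["panel_meta"], sep="\t", index=False)

    spat = _syn.gen_spatial_panel(
        n_flocks=20, flock_size=8, cline=_syn.ClineSpec(), seed=seed + 1
    )
    paths["spatial_table"] = out / "synthetic_spatial.tsv"
    spat.to_csv(paths["spatial_table"], sep="\t", index=False)
    return paths
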