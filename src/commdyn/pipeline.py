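"""End-to-end orchestration on synthetic data.

``run_pipeline`` mirrors the analysis shape of a longitudinal cross-domain
community study: simulate a known-ground-truth community -> sample coverage
counts -> TPM-normalize -> occurrence-filter -> aggregate to phylum ->
diversity and per-domain ordination -> Procrustes congruence across domains
-> S-map interaction inference -> association report.

All randomness flows from one root seed.  Stage seeds are expanded as
``SeedSequence([root_seed, stage_index]).generate_state(1)[0] % 2**31``
(stage indices are fixed and listed in the manifest), so every stage is
independently reproducible.  Rerunning with the same root seed yields
byte-identical numeric tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance, associations, diversity, io, ordination, procrustes, smap, synthetic
from .containers import CommunityTimeSeries

logger = logging.getLogger(__name__)

STAGE_INDICES = {
    "simulate": 0,
    "coverage": 1,
    "metadata": 2,
    "ordination": 3,
    "protest": 4,
    "smap": 5,
    "associations": 6,
}


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed expansion from the root seed."""
    ss = np.random.SeedSequence([int(root_seed), STAGE_INDICES[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Settings for the demo pipeline; defaults emulate the study layout:
    a monthly, multi-year, multi-domain community with seasonal forcing, a
    one-off mortality pulse, a sustained salinity dip and finite-library
    sampling noise."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    n_taxa: int = 12
    n_samples: int = 143
    library_size: int = 100_000
    intervention_month: int = 30
    intervention_survival: float = 0.3
    occurrence_min_fraction: float = 0.10
    nmds_starts: int = 10
    n_permutations: int = 999
    smap_theta: float = 1.0
    smap_lambda: float = 0.01
    smap_alpha: float = 0.5
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate", "normalize", "diversity", "ordination",
            "procrustes", "smap", "associations",
        ]
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# stage -> stages it needs
_DEPENDS = {
    "simulate": [],
    "normalize": ["simulate"],
    "diversity": ["normalize"],
    "ordination": ["normalize"],
    "procrustes": ["ordination"],
    "smap": ["normalize"],
    "associations": ["simulate", "normalize", "ordination"],
}

_DOMAIN_CYCLE = ["prokaryote", "prokaryote", "eukaryote", "virus"]


def _demo_community(cfg: PipelineConfig) -> tuple[CommunityTimeSeries, synthetic.GLVParams]:
    domains = [_DOMAIN_CYCLE[i % len(_DOMAIN_CYCLE)] for i in range(cfg.n_taxa)]
    params = synthetic.random_stable_params(
        cfg.n_taxa, seed=stage_seed(cfg.seed, "simulate"), domain_labels=domains
    )
    rng = np.random.default_rng(stage_seed(cfg.seed, "simulate"))
    x0 = rng.uniform(0.5, 1.5, cfg.n_taxa)
    pulse = synthetic.InterventionSpec(
        time_index=cfg.intervention_month,
        affected_taxa=[i for i, d in enumerate(domains) if d != "eukaryote"][:4],
        survival_fraction=cfg.intervention_survival,
    )
    series = synthetic.simulate_glv(
        params, cfg.n_samples, x0, seed=stage_seed(cfg.seed, "simulate"), intervention=pulse
    )
    return series, params


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns a manifest dict (also written to
    ``manifest.json``).  A failed stage halts only its dependents."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": asdict(config),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGE_INDICES},
        "stages": {},
    }
    done: set[str] = set()
    state: dict = {}
    summary_lines: list[str] = []

    for stage in config.stages:
        missing = [d for d in _DEPENDS.get(stage, []) if d in config.stages and d not in done]
        if missing:
            manifest["stages"][stage] = {"status": "skipped", "missing_dependencies": missing}
            continue
        t0 = time.time()
        try:
            _run_stage(stage, config, state, out, summary_lines)
        except Exception as exc:  # halt downstream dependents only
            logger.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = {"status": "failed", "error": f"{stage}: {exc}"}
            continue
        done.add(stage)
        manifest["stages"][stage] = {"status": "ok", "seconds": round(time.time() - t0, 3)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return manifest


def _run_stage(stage, cfg: PipelineConfig, state: dict, out: Path, summary: list[str]) -> None:
    if stage == "simulate":
        series, params = _demo_community(cfg)
        counts = synthetic.sample_coverage(
            series,
            cfg.library_size,
            feature_lengths=np.linspace(1000, 5000, cfg.n_taxa),
            seed=stage_seed(cfg.seed, "coverage"),
        )
        meta = synthetic.simulate_metadata(series, seed=stage_seed(cfg.seed, "metadata"))
        state.update(series=series, params=params, counts=counts, metadata=meta)
        io.write_table(series.to_frame(), out / "true_abundance.tsv")
        io.write_table(counts, out / "coverage_counts.tsv")
        io.write_table(meta, out / "metadata.tsv", index_label="parameter")
        io.write_taxonomy(
            series.taxon_ids,
            series.domain_labels,
            [f"phylum_{i % 8}" for i in range(series.n_taxa)],
            out / "taxonomy.tsv",
        )
        summary.append(
            f"simulate: {series.n_taxa} taxa x {series.n_time} monthly samples; "
            f"pulse at month {cfg.intervention_month}"
        )
    elif stage == "normalize":
        tpm = abundance.tpm_normalize(state["counts"], np.linspace(1000, 5000, cfg.n_taxa))
        filtered = abundance.occurrence_filter(tpm, cfg.occurrence_min_fraction)
        state["tpm"] = filtered
        io.write_table(filtered, out / "tpm_filtered.tsv")
        summary.append(
            f"normalize: TPM columns sum to 1e6; {filtered.shape[0]}/{tpm.shape[0]} "
            f"taxa pass the >{cfg.occurrence_min_fraction:.0%} occurrence filter"
        )
    elif stage == "diversity":
        alpha = diversity.alpha_series(state["tpm"])
        state["alpha"] = alpha
        io.write_table(alpha, out / "alpha_diversity.tsv", index_label="sample_id")
        summary.append(
            f"diversity: mean richness {alpha['richness'].mean():.1f}, "
            f"mean Pielou {alpha['pielou'].mean():.3f}"
        )
    elif stage == "ordination":
        series = state["series"]
        domains = pd.Series(series.domain_labels, index=series.taxon_ids)
        state["ordinations"] = {}
        state["distances"] = {}
        for dom in ["eukaryote", "prokaryote", "virus"]:
            taxa = [t for t in state["tpm"].index if domains.get(t) == dom]
            if len(taxa) < 2:
                continue
            dist = ordination.bray_curtis(state["tpm"].loc[taxa])
            ordn = ordination.nmds(
                dist, k=2, n_starts=cfg.nmds_starts, seed=stage_seed(cfg.seed, "ordination")
            )
            pco = ordination.pcoa(dist, k=2)
            state["distances"][dom] = dist
            state["ordinations"][dom] = ordn
            io.write_distance_matrix(dist, out / f"bray_curtis_{dom}.tsv")
            io.write_table(ordn.to_frame(), out / f"nmds_{dom}.tsv", index_label="sample_id")
            io.write_table(pco.to_frame(), out / f"pcoa_{dom}.tsv", index_label="sample_id")
            summary.append(f"ordination[{dom}]: NMDS stress {ordn.stress:.4f}")
    elif stage == "procrustes":
        doms = sorted(state["ordinations"])
        rows = []
        for i in range(len(doms)):
            for j in range(i + 1, len(doms)):
                a, b = doms[i], doms[j]
                res = procrustes.protest(
                    state["ordinations"][a].coordinates,
                    state["ordinations"][b].coordinates,
                    n_permutations=cfg.n_permutations,
                    seed=stage_seed(cfg.seed, "protest"),
                )
                rows.append(
                    {"config_a": a, "config_b": b, "m_squared": res.m_squared,
                     "p_value": res.p_value, "n_permutations": res.n_permutations}
                )
                summary.append(
                    f"procrustes[{a} vs {b}]: M2={res.m_squared:.4f} p={res.p_value:.3f}"
                )
        io.write_table(pd.DataFrame(rows), out / "procrustes.tsv", index_label="row")
    elif stage == "smap":
        tpm = state["tpm"]
        series = CommunityTimeSeries.from_frame(tpm)
        hyper = smap.SMapHyperparams(
            theta=cfg.smap_theta, lam=cfg.smap_lambda, alpha=cfg.smap_alpha
        )
        jac = smap.infer_interactions(series, hyper)
        table = jac.to_long_frame()
        summary_table = smap.summarize_interactions(jac)
        state["jacobians"] = jac
        io.write_table(table, out / "jacobians_long.tsv", index_label="row")
        io.write_table(summary_table, out / "interaction_summary.tsv", index_label="row")
        n_pairs = (summary_table["pair_type"] == "exploitation").sum() // 2
        summary.append(
            f"smap: theta={hyper.theta} lambda={hyper.lam} alpha={hyper.alpha}; "
            f"{n_pairs} exploitation pair(s) flagged"
        )
    elif stage == "associations":
        corr = associations.pearson_screen(state["tpm"], state["metadata"])
        io.write_table(corr, out / "pearson_screen.tsv", index_label="row")
        doms = sorted(state["distances"])
        rows = []
        for i in range(len(doms)):
            for j in range(i + 1, len(doms)):
                r, p = associations.mantel(
                    state["distances"][doms[i]], state["distances"][doms[j]],
                    n_permutations=cfg.n_permutations,
                    seed=stage_seed(cfg.seed, "associations"),
                )
                rows.append({"d1": doms[i], "d2": doms[j], "mantel_r": r, "p": p})
        io.write_table(pd.DataFrame(rows), out / "mantel.tsv", index_label="row")
        # wet season (May-Oct) vs dry season; series starts in June
        cal_month = (5 + np.asarray(state["series"].time_stamps, dtype=int)) % 12 + 1
        season = np.where((cal_month >= 5) & (cal_month <= 10), "wet", "dry")
        anydom = doms[0]
        f, r2, p = associations.permanova(
            state["distances"][anydom], season,
            n_permutations=cfg.n_permutations,
            seed=stage_seed(cfg.seed, "associations"),
        )
        io.write_table(
            pd.DataFrame([{"factor": "season", "pseudo_F": f, "R2": r2, "p": p}]),
            out / "permanova.tsv", index_label="row",
        )
        summary.append(f"associations: season PERMANOVA F={f:.2f} R2={r2:.3f} p={p:.3f}")
        n_sig = (corr["p_adjusted"] < 0.05).sum()
        summary.append(f"associations: {n_sig} Bonferroni-significant taxon-covariate pairs")
    else:
        raise ValueError(f"unknown stage {stage!r}")


# ---------------------------------------------------------------------------
# fixtures

_ALIGNMENT_FIXTURE = [
    # read_id, target_id, domain, alignment_score
    ("r01", "euk_c1", "eukaryote", 60), ("r01", "prok_c1", "prokaryote", 40),
    ("r02", "prok_c2", "prokaryote", 55), ("r02", "vir_c1", "virus", 20),
    ("r03", "vir_c2", "virus", 70),
    ("r04", "euk_c2", "eukaryote", 50), ("r04", "euk_c3", "eukaryote", 50),
    ("r04", "prok_c3", "prokaryote", 30),
    ("r05", "euk_c4", "eukaryote", 60), ("r05", "prok_c4", "prokaryote", 60),
    ("r06", "prok_c5", "prokaryote", 45), ("r06", "vir_c3", "virus", 45),
    ("r07", "euk_c5", "eukaryote", 33), ("r07", "prok_c6", "prokaryote", 33),
    ("r07", "vir_c4", "virus", 33),
    ("r08", "prok_c7", "prokaryote", 80), ("r08", "prok_c8", "prokaryote", 60),
    ("r09", "euk_c6", "eukaryote", 90), ("r09", "vir_c5", "virus", 10),
    ("r10", "vir_c6", "virus", 65), ("r10", "prok_c9", "prokaryote", 64),
]

#: Expected classification of the bundled 10-read digest: 3 cross-domain
#: equal-top reads are unclassified, one within-domain tie stays assigned.
ALIGNMENT_FIXTURE_EXPECTED = {
    "assigned": {
        "r01": "eukaryote", "r02": "prokaryote", "r03": "virus", "r04": "eukaryote",
        "r08": "prokaryote", "r09": "eukaryote", "r10": "virus",
    },
    "unclassified": ["r05", "r06", "r07"],
}


def make_fixtures(out_dir, seed: int = 0) -> list[Path]:
    """Write the small worked-example tables used throughout the tests.

    Deterministic and idempotent: regenerating restores byte-identical
    files.  Returns the list of paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    digest = pd.DataFrame(
        _ALIGNMENT_FIXTURE, columns=["read_id", "target_id", "domain", "alignment_score"]
    )
    p = out / "alignment_digest.tsv"
    digest.to_csv(p, sep="\t", index=False)
    written.append(p)

    toy = pd.DataFrame(
        {"2018-01": [10, 10, 0], "2018-02": [10, 0, 5], "2018-03": [0, 4, 6], "2018-04": [2, 2, 2]},
        index=pd.Index(["taxon_a", "taxon_b", "taxon_c"], name="taxon_id"),
    )
    p = out / "toy_abundance.tsv"
    toy.to_csv(p, sep="\t")
    written.append(p)

    n = 4  # regular-simplex distances: all off-diagonal 1
    simplex = pd.DataFrame(
        np.ones((n, n)) - np.eye(n),
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        columns=[f"s{i}" for i in range(n)],
    )
    p = out / "simplex_distance.tsv"
    simplex.to_csv(p, sep="\t", float_format="%.1f")
    written.append(p)
    return written
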