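"""End-to-end orchestration: instruments → MR → Bonferroni gate → coloc
gate → directionality → prioritization, with a provenance manifest.

The funnel is monotone by construction: every prioritized target passed
every upstream gate, and the manifest records per-stage row counts, the
thresholds applied, input file hashes and the seed, so identical inputs
yield an identical manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import mr
from .directionality import r_from_assoc, steiger_test
from .instruments import clump, make_instrument, mask_mhc, significance_filter
from .prioritize import prioritize, read_annotations, report
from .sumstats import read_ld_matrix, read_sumstats, harmonize

logger = logging.getLogger("neurotarget")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run."""

    eqtl_path: str
    gwas_path: str
    ld_path: str
    out_dir: str
    annotations_path: str | None = None
    trait_id: str = "disease"
    p_instrument: float = 5e-8
    r2_threshold: float = 0.001
    window_mb: float = 10.0
    alpha: float = 0.05
    pp4_threshold: float = 0.70
    het_p: float = 0.001
    phewas_alpha: float = 0.05
    coloc_p1: float = 5e-4
    coloc_p2: float = 5e-4
    coloc_p12: float = 5e-5
    half_window_kb: float = 500.0
    mask_mhc: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pp4_threshold < 1):
            raise ValueError("pp4_threshold must be in (0, 1)")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.p_instrument <= 0 or self.r2_threshold < 0:
            raise ValueError("invalid instrument thresholds")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns the run manifest.

    Stage outputs are written under ``config.out_dir`` as TSV, plus
    ``manifest.json``. A stage failure raises with the stage name in the
    message; outputs written so far are left in place.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "thresholds": {
            k: v for k, v in asdict(cfg).items()
            if isinstance(v, (int, float, bool)) and k != "seed"
        },
        "seed": cfg.seed,
        "counts": {},
    }
    counts = manifest["counts"]

    # -- stage: read ---------------------------------------------------
    try:
        manifest["inputs"] = {
            name: _sha256(p)
            for name, p in (
                ("eqtl", cfg.eqtl_path),
                ("gwas", cfg.gwas_path),
                ("ld", cfg.ld_path),
            )
        }
        eqtl = read_sumstats(cfg.eqtl_path, trait_id="expression")
        gwas = read_sumstats(cfg.gwas_path, trait_id=cfg.trait_id)
        ld = read_ld_matrix(cfg.ld_path)
    except Exception as exc:
        raise RuntimeError(f"stage 'read' failed: {exc}") from exc
    counts["eqtl_records"] = len(eqtl)
    counts["gwas_records"] = len(gwas)

    # -- stage: instrument selection -----------------------------------
    try:
        pool = mask_mhc(eqtl) if cfg.mask_mhc else list(eqtl)
        counts["after_mhc_mask"] = len(pool)
        pool = significance_filter(pool, cfg.p_instrument)
        counts["genome_wide_significant"] = len(pool)
        by_gene: dict[str, list] = {}
        for rec in pool:
            by_gene.setdefault(rec.gene_id or "", []).append(rec)
        instruments = []
        for gene_id in sorted(by_gene):
            for rec in clump(
                by_gene[gene_id], ld, cfg.r2_threshold, int(cfg.window_mb * 1e6)
            ):
                instruments.append(make_instrument(rec))
        counts["instruments"] = len(instruments)
    except Exception as exc:
        raise RuntimeError(f"stage 'instruments' failed: {exc}") from exc

    # -- stage: MR + Bonferroni gate -----------------------------------
    try:
        gwas_by_id = {r.variant_id: r for r in gwas}
        wald_results = []
        pairs = []
        for inst in instruments:
            outcome = gwas_by_id.get(inst.variant_id)
            if outcome is None:
                continue
            pair = harmonize(inst.record, outcome)
            if pair.dropped:
                continue
            wald_results.append((inst, mr.wald_ratio(inst, pair.outcome)))
        n_tests = max(len(wald_results), 1)
        bonf = mr.bonferroni_threshold(cfg.alpha, n_tests)
        wald_results = [
            (inst, mr.WaldResult(
                w.gene_id, w.trait_id, w.variant_id, w.wr, w.se, w.p,
                passes_bonferroni=w.p < bonf,
            ))
            for inst, w in wald_results
        ]
        counts["mr_tests"] = len(wald_results)
        counts["bonferroni_threshold"] = bonf
        survivors = [(i, w) for i, w in wald_results if w.passes_bonferroni]
        counts["bonferroni_survivors"] = len(survivors)
    except Exception as exc:
        raise RuntimeError(f"stage 'mr' failed: {exc}") from exc

    # -- stage: colocalization gate ------------------------------------
    try:
        priors = coloc_mod.ColocPriors(p1=cfg.coloc_p1, p2=cfg.coloc_p2, p12=cfg.coloc_p12)
        eqtl_by_gene: dict[str, list] = {}
        for rec in eqtl:
            eqtl_by_gene.setdefault(rec.gene_id or "", []).append(rec)
        coloc_hits = []
        coloc_rows = []
        for inst, w in survivors:
            cres = coloc_mod.run_coloc(
                eqtl_by_gene[inst.gene_id], gwas, inst.variant_id,
                priors=priors, half_window_bp=int(cfg.half_window_kb * 1e3),
            )
            passed = coloc_mod.coloc_pass(cres, cfg.pp4_threshold)
            coloc_rows.append({
                "gene_id": w.gene_id, "variant_id": w.variant_id,
                "pp0": cres.pp0, "pp1": cres.pp1, "pp2": cres.pp2,
                "pp3": cres.pp3, "pp4": cres.pp4, "n_snps": cres.n_snps,
                "pass": passed,
            })
            if passed:
                coloc_hits.append((inst, w, cres))
        counts["coloc_survivors"] = len(coloc_hits)
    except Exception as exc:
        raise RuntimeError(f"stage 'coloc' failed: {exc}") from exc

    # -- stage: directionality -----------------------------------------
    try:
        steiger_rows = []
        for inst, w, cres in coloc_hits:
            outcome = gwas_by_id[inst.variant_id]
            res = steiger_test(
                r_from_assoc(inst.record, "quantitative"), inst.record.n,
                r_from_assoc(outcome, "binary"), outcome.n,
            )
            steiger_rows.append({
                "gene_id": w.gene_id, "variant_id": w.variant_id,
                "r_gx": res.r_gx, "r_gy": res.r_gy,
                "direction_correct": res.direction_correct,
                "p_steiger": res.p_steiger,
            })
        counts["steiger_direction_correct"] = sum(
            1 for r in steiger_rows if r["direction_correct"]
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'directionality' failed: {exc}") from exc

    # -- stage: prioritization -----------------------------------------
    try:
        annotations = (
            read_annotations(cfg.annotations_path) if cfg.annotations_path else {}
        )
        calls = prioritize([(w, cres) for _, w, cres in coloc_hits], annotations)
        counts["prioritized_targets"] = sum(1 for c in calls if c.top_ranked)
    except Exception as exc:
        raise RuntimeError(f"stage 'prioritize' failed: {exc}") from exc

    # -- stage: outputs ------------------------------------------------
    inst_df = pd.DataFrame([
        {
            "gene_id": i.gene_id, "variant_id": i.variant_id,
            "chrom": i.record.chrom, "pos": i.record.pos,
            "z": i.z, "beta_std": i.beta_std, "se_std": i.se_std,
            "pve": i.pve, "f_stat": i.f_stat,
        }
        for i in instruments
    ])
    mr_df = pd.DataFrame([
        {
            "gene_id": w.gene_id, "trait_id": w.trait_id,
            "variant_id": w.variant_id, "wr": w.wr, "se": w.se, "p": w.p,
            "passes_bonferroni": w.passes_bonferroni,
        }
        for _, w in wald_results
    ])
    inst_df.to_csv(out / "instruments.tsv", sep="\t", index=False)
    mr_df.to_csv(out / "mr_results.tsv", sep="\t", index=False)
    pd.DataFrame(coloc_rows).to_csv(out / "coloc.tsv", sep="\t", index=False)
    pd.DataFrame(steiger_rows).to_csv(out / "steiger.tsv", sep="\t", index=False)
    report(calls).to_csv(out / "report.tsv", sep="\t", index=False)
    pd.DataFrame([
        {
            "gene_id": c.gene_id, "indication": c.indication,
            "action": c.action, "top_ranked": c.top_ranked,
            "criteria_met": ",".join(sorted(c.criteria_met)),
        }
        for c in calls
    ]).to_csv(out / "targets.tsv", sep="\t", index=False)

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info(
        "funnel: %d instruments -> %d MR tests -> %d Bonferroni -> %d coloc -> %d prioritized",
        counts["instruments"], counts["mr_tests"],
        counts["bonferroni_survivors"], counts["coloc_survivors"],
        counts["prioritized_targets"],
    )
    return manifest
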