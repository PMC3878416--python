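"""End-to-end driver: design -> simulate -> fit -> rank.

Each invocation writes one run directory containing the designs, the
phenotype table, per-model fit summaries, rankings, the concordance
report and a manifest with input checksums and stage seeds, so a run is
fully reproducible from its configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io as mio
from .config import PipelineConfig
from .designs import generate_field_design, generate_lab_design
from .mixed_model import FitOptions, fit_reml, lrt, spec_model
from .ranking import concordance_report, scatter_frame
from .simulate import simulate_met

log = logging.getLogger("metphase")

_NESTED_PAIRS = [("A", "B"), ("B", "C"), ("A", "C")]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    cfg: PipelineConfig, out_dir, fit_opts: FitOptions | None = None
) -> Path:
    """Run the full workflow; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "files": {}}
    root_seq = np.random.SeedSequence(cfg.seed)
    seeds = {
        name: int(s.generate_state(1)[0])
        for name, s in zip(
            ("field", "lab", "availability", "simulate"), root_seq.spawn(4)
        )
    }
    manifest["stage_seeds"] = seeds

    t0 = time.time()
    cultivar_lists = cfg.cultivar_lists()
    field_designs, lab_designs = {}, {}
    avail_rng = np.random.default_rng(seeds["availability"])
    for t in cfg.trials:
        cvs = cultivar_lists[t.name]
        fd = generate_field_design(
            cvs, n_blocks=t.n_blocks, n_rows=t.n_rows, seed=seeds["field"], trial=t.name
        )
        field_designs[t.name] = fd
        n_avail = t.available_per_block or len(cvs)
        available = {
            b: sorted(avail_rng.choice(cvs, size=n_avail, replace=False))
            for b in range(1, t.n_blocks + 1)
        }
        lab_designs[t.name] = generate_lab_design(
            available,
            dup_count=t.dup_count,
            plates_per_day=t.plates_per_day,
            seed=seeds["lab"],
            trial=t.name,
        )
        mio.write_field_design(fd, out / f"field_{t.name}.csv")
        mio.write_lab_design(lab_designs[t.name], out / f"lab_{t.name}.csv")
    manifest["stages"]["design"] = {"seconds": round(time.time() - t0, 2)}
    log.info("designs generated (%.1fs)", time.time() - t0)

    t0 = time.time()
    table = simulate_met(
        field_designs,
        lab_designs,
        cfg.variance_components(),
        cfg.trial_means(),
        seed=seeds["simulate"],
    )
    pheno_path = out / "phenotypes.csv"
    mio.write_phenotypes(table, pheno_path)
    manifest["stages"]["simulate"] = {
        "seconds": round(time.time() - t0, 2),
        "records": int(len(table)),
    }
    log.info("simulated %d wells (%.1fs)", len(table), time.time() - t0)

    term_lists = {t.name: list(t.terms) for t in cfg.trials}
    fits = {}
    for kind in cfg.models:
        t0 = time.time()
        spec = spec_model(kind, table, None if kind == "A" else term_lists)
        try:
            fits[kind] = fit_reml(spec, table, fit_opts)
        except Exception:
            manifest["stages"][f"fit_{kind}"] = {"failed": True}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            log.exception("stage fit_%s failed; partial state persisted", kind)
            raise
        mio.write_fit(fits[kind], out / f"fit_{kind}.json", out / f"eblups_{kind}.csv")
        manifest["stages"][f"fit_{kind}"] = {
            "seconds": round(time.time() - t0, 2),
            "loglik": fits[kind].loglik,
        }
        log.info("model %s fitted (%.1fs)", kind, time.time() - t0)

    summary: dict = {"models": {}, "lrt": {}}
    for kind, fit in fits.items():
        summary["models"][kind] = mio.read_fit(out / f"fit_{kind}.json")
    for nested_k, full_k in _NESTED_PAIRS:
        if nested_k in fits and full_k in fits:
            stat, df, p = lrt(fits[nested_k], fits[full_k])
            summary["lrt"][f"{full_k}_vs_{nested_k}"] = {
                "statistic": stat,
                "df": df,
                "p_value": p,
            }

    report = concordance_report(fits, k=cfg.k)
    summary["concordance"] = report
    (out / "concordance.json").write_text(json.dumps(report, indent=2))
    for kind, fit in fits.items():
        if len(fit.trials) == 2:
            scatter_frame(fit, k=cfg.k).to_csv(out / f"scatter_{kind}.csv", index=False)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
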