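"""End-to-end pipeline: calibrate, segment, measure, fit, and report.

:func:`run_pipeline` runs every analysis stage over a transmission chain —
loaded from disk or freshly simulated — and writes one CSV per stage plus a
per-generation summary and a JSON manifest (configuration, seeds, threshold,
compressor) sufficient to reproduce the run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .abbrev_rt import build_rt_table, filter_rts, poisson_freq_length, rt_tp_association
from .baselines import baseline_comparison
from .complexity import COMPRESSOR, kolmogorov_estimate
from .distfit import compare_families
from .metrics import rank_table, set_summary, transmission_error, unit_inventory
from .seqdata import TransmissionChain, read_chain, write_chain, write_events
from .segmentation import TrigramModel, calibrate_threshold, segment_set
from .synthetic import ChainSimConfig, simulate_chain

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _units_table(chain: TransmissionChain, threshold: float) -> pd.DataFrame:
    rows = []
    for g, sset in enumerate(chain):
        seg = segment_set(sset, threshold)
        table = rank_table(unit_inventory(seg))
        table.insert(0, "generation", g)
        table.insert(0, "chain_id", sset.chain_id or "")
        rows.append(table)
    return pd.concat(rows, ignore_index=True)


def run_pipeline(
    source: str | Path | ChainSimConfig,
    out_dir: str | Path,
    threshold: float | str = "calibrate",
    reps: int = 50,
    seed: int = 0,
    calibration_sets: int = 500,
) -> dict:
    """Run the full analysis over a chain and write a report bundle.

    Parameters
    ----------
    source
        Path to a chain (directory of ``genNN.txt`` or chain CSV), or a
        :class:`~seqchains.synthetic.ChainSimConfig` to simulate one.
    out_dir
        Output directory (created if missing).
    threshold
        Segmentation threshold, or ``"calibrate"`` to recompute it from
        *calibration_sets* random sets.
    reps
        Replicates per null baseline.
    seed
        Master seed for calibration and baseline randomness.

    Returns the manifest dictionary; all stage outputs are CSV files in
    *out_dir*.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__ as _v  # late import; __init__ imports this module
    manifest: dict = {"package_version": _v, "seed": int(seed),
                      "compressor": COMPRESSOR, "reps": int(reps)}

    # --- stage: chain -----------------------------------------------------
    events_by_gen: dict = {}
    if isinstance(source, ChainSimConfig):
        logger.info("simulating chain: %s", source)
        chain, events_by_gen = simulate_chain(source)
        write_chain(chain, out / "chain")
        all_events = [ev for evs in events_by_gen.values() for ev in evs]
        write_events(all_events, out / "events.csv")
        manifest["source"] = {"simulated": dataclasses.asdict(source)}
    else:
        chain = read_chain(source)
        manifest["source"] = {"path": str(source)}
    logger.info("chain %s: %d generations", chain.chain_id, len(chain))

    # --- stage: threshold -------------------------------------------------
    if threshold == "calibrate":
        threshold = calibrate_threshold(
            n_sets=calibration_sets, alphabet=chain.alphabet, seed=seed
        )
        logger.info("calibrated threshold: %.4f", threshold)
        manifest["threshold"] = {"value": threshold, "calibrated": True,
                                 "n_sets": calibration_sets}
    else:
        threshold = float(threshold)
        manifest["threshold"] = {"value": threshold, "calibrated": False}

    # --- stage: per-set metrics ------------------------------------------
    seg_by_gen = {g: segment_set(sset, threshold) for g, sset in enumerate(chain)}
    rows = []
    for g, sset in enumerate(chain):
        row = set_summary(seg_by_gen[g])
        row["complexity"] = kolmogorov_estimate(sset)
        if g >= 1:
            prev = chain[g - 1]
            n = min(len(prev), len(sset))
            errs = [transmission_error(prev[i], sset[i]) for i in range(n)]
            row["mean_error"] = float(np.mean(errs))
            row["pct_correct"] = 100.0 * float(np.mean([e == 0 for e in errs]))
        else:
            row["mean_error"] = np.nan
            row["pct_correct"] = np.nan
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "metrics.csv", index=False)
    logger.info("metrics: %d generation rows", len(summary))

    # --- stage: units + distribution fits --------------------------------
    units = _units_table(chain, threshold)
    units.to_csv(out / "units.csv", index=False)
    fit_rows = []
    for g in range(len(chain)):
        sub = units[units["generation"] == g]
        if sub["frequency"].size < 2:
            continue
        for fit in compare_families(sub["frequency"].to_numpy()):
            fit_rows.append(
                {"generation": g, "family": fit.family,
                 "param": next(iter(fit.params.values()), np.nan),
                 "loglik": fit.loglik, "aic": fit.aic, "rel_prob": fit.rel_prob}
            )
    pd.DataFrame(fit_rows).to_csv(out / "distfits.csv", index=False)

    # --- stage: baselines -------------------------------------------------
    baselines = baseline_comparison(chain, threshold, n_reps=reps, seed=seed)
    baselines.to_csv(out / "baselines.csv", index=False)
    logger.info("baselines: %d rows (%d reps per null)", len(baselines), reps)

    # --- stage: abbreviation ----------------------------------------------
    abbrev_rows = []
    if units["length"].nunique() >= 2:
        fit = poisson_freq_length(units, formula="length_x_generation")
        for name in fit.params:
            abbrev_rows.append({"model": "length_x_generation", "term": name,
                                "estimate": fit.params[name], "se": fit.bse[name],
                                "z": fit.tvalues[name]})
        units_flag = units.assign(is_produced=(units["generation"] >= 1).astype(int))
        fit = poisson_freq_length(units_flag, formula="length_x_produced")
        for name in fit.params:
            abbrev_rows.append({"model": "length_x_produced", "term": name,
                                "estimate": fit.params[name], "se": fit.bse[name],
                                "z": fit.tvalues[name]})
    pd.DataFrame(abbrev_rows).to_csv(out / "abbreviation.csv", index=False)

    # --- stage: reaction times (simulated chains only) --------------------
    if events_by_gen:
        all_events = [ev for evs in events_by_gen.values() for ev in evs]
        _, rt_report = filter_rts(all_events)
        models = {g: TrigramModel.fit(chain[g - 1]) for g in events_by_gen}
        rt_table = build_rt_table(all_events, models)
        rt_fit = rt_tp_association(rt_table)
        rt_rows = [
            {"term": name, "estimate": rt_fit.params[name],
             "se": rt_fit.bse[name], "t": rt_fit.tvalues[name]}
            for name in rt_fit.params
        ]
        pd.DataFrame(rt_rows).to_csv(out / "rt_association.csv", index=False)
        manifest["rt_filter"] = rt_report
        logger.info("rt: kept %d of %d keypresses", rt_report["n_kept"], rt_report["n_input"])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                             encoding="utf-8")
    return manifest
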