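"""End-to-end experiment runners.

Each ``run_expN`` takes a flat configuration dictionary (every random
operation receives an explicit seed derived from ``config["seed"]``),
simulates or loads a cohort, executes the full analysis chain of that
experiment, and returns a JSON-serializable bundle: per-participant tables
plus group-level statistics, with the resolved configuration and exclusion
counts embedded so a run can be replayed exactly.

Units throughout: angles deg, time ms, velocity deg/s, contrast Michelson.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np
import pandas as pd

from . import psychometric as pmf
from . import synthetic as syn
from .inferential import linregress, t_test, wilcoxon_signed_rank
from .pursuit import (DETECTION_FILTER, FilterSpec, desaccade,
                      detect_saccades, differentiate_and_filter,
                      mean_pursuit_velocity, oculometric_decision)
from .quest import attentional_imbalance, quest_estimate
from .resampling import (AlignedTimecourses, align_to_reversals,
                         cluster_permutation, distance_to_region,
                         gaze_label_permutation)
from .sdt import SDTCounts, dprime_criterion, residualize_dprime

__all__ = ["run_exp1", "run_exp2", "run_exp3", "run_exp4",
           "load_config", "save_bundle"]


def load_config(path) -> dict:
    """Flat key-value YAML config."""
    import yaml
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat mapping")
    return cfg


def _json_default(o):
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def save_bundle(bundle: dict, out_dir) -> None:
    """Write the stats record (JSON) and per-participant table (CSV)."""
    os.makedirs(out_dir, exist_ok=True)
    tables = {k: v for k, v in bundle.items() if isinstance(v, pd.DataFrame)}
    rest = {k: v for k, v in bundle.items() if not isinstance(v, pd.DataFrame)}
    with open(os.path.join(out_dir, "stats.json"), "w") as f:
        json.dump(rest, f, indent=2, default=_json_default)
    for name, df in tables.items():
        df.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)


def _sdt_counts(em: pd.DataFrame, location: str) -> SDTCounts:
    sel = em[em.probe_location == location]
    sig = sel[sel.digit_present.astype(bool)]
    noi = sel[~sel.digit_present.astype(bool)]
    return SDTCounts(
        hits=int(sig.response_present.sum()),
        misses=int(len(sig) - sig.response_present.sum()),
        false_alarms=int(noi.response_present.sum()),
        correct_rejections=int(len(noi) - noi.response_present.sum()))


def run_exp1(config: dict) -> dict:
    """Digit-detection chain: SDT per location, QUEST thresholds and
    attentional imbalance, endpoint statistics, gaze-residualized d'."""
    seed = int(config.get("seed", 0))
    n = int(config.get("n_participants", 60))
    base = syn.ObserverExp1(**config.get("observer", {}))
    between = config.get("between")
    cohort = syn.sample_cohort(base, n, seed, between)
    part_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence(seed + 1).spawn(n)]
    overrides = config.get("overrides", {})

    rows = []
    for i, (obs, ps) in enumerate(zip(cohort, part_seeds)):
        sess = syn.gen_exp1_session(obs, syn.SessionSpec(
            experiment_id=1, seed=ps, overrides=overrides))
        em = sess.em_trials
        r = {"participant": i, "seed": ps, "total_score": int(sess.trials.score.sum())}
        for loc in ("high", "low"):
            res = dprime_criterion(_sdt_counts(em, loc))
            r[f"dprime_{loc}"] = res.dprime
            r[f"criterion_{loc}"] = res.criterion
            r[f"threshold_{loc}"] = quest_estimate(sess.quest_states[loc])
        r["imbalance"] = attentional_imbalance(r["threshold_low"],
                                               r["threshold_high"])
        r["mean_endpoint"] = float(em.endpoint_y.mean())
        rows.append(r)
    per = pd.DataFrame(rows)

    resid = residualize_dprime(per.dprime_high.to_numpy(),
                               per.dprime_low.to_numpy(),
                               per.mean_endpoint.to_numpy(), sides="two-sided")
    group = {
        "criterion_high_vs_0": t_test(per.criterion_high, mu0=0.0, sides="less"),
        "criterion_low_vs_0": t_test(per.criterion_low, mu0=0.0, sides="greater"),
        "criterion_high_vs_low": t_test(per.criterion_high, per.criterion_low,
                                        paired=True, sides="less"),
        "dprime_high_vs_low": t_test(per.dprime_high, per.dprime_low,
                                     paired=True, sides="greater"),
        "endpoint_vs_0": t_test(per.mean_endpoint, mu0=0.0, sides="greater"),
        "imbalance_vs_0": t_test(per.imbalance, mu0=0.0, sides="greater"),
        "dprime_high_on_endpoint": linregress(per.dprime_high, per.mean_endpoint),
        "dprime_low_on_endpoint": linregress(per.dprime_low, per.mean_endpoint),
        "residual_dprime_test": resid.residual_test,
        "dprime_reduction_test": resid.reduction_test,
    }
    return {"experiment": 1, "config": {"seed": seed, "n_participants": n,
                                        "overrides": overrides},
            "participants": per, "group": group,
            "residual_slopes": resid.slopes,
            "residual_intercepts": resid.intercepts}


def _analyze_exp2_participant(sess: syn.Exp2Session, filter_spec: FilterSpec,
                              seed: int) -> dict | None:
    """Per-trial pursuit velocities -> oculometric decisions -> 8 fits ->
    the two bias indices.  Returns None when any required fit fails."""
    des = sess.design.copy()
    tie_rng = np.random.default_rng(seed)
    if sess.traces:
        v1 = np.empty(len(des))
        v2 = np.empty(len(des))
        for i, (tr1, tr2) in enumerate(sess.traces):
            for j, tr in enumerate((tr1, tr2)):
                vel = differentiate_and_filter(tr, filter_spec)
                vel_det = differentiate_and_filter(tr, DETECTION_FILTER)
                ev = detect_saccades(vel_det, trace=tr)
                vel = desaccade(vel, ev)
                v, _lowq = mean_pursuit_velocity(vel)
                (v1 if j == 0 else v2)[i] = v
    else:   # velocity-summary fast path (generative perceived velocities)
        v1 = sess.observer.pursuit_gain * des.perceived_first.to_numpy()
        v2 = sess.observer.pursuit_gain * des.perceived_second.to_numpy()
    des["pursuit_first"] = v1
    des["pursuit_second"] = v2
    std_first = des.order == "standard_first"
    v_std = np.where(std_first, v1, v2)
    v_cmp = np.where(std_first, v2, v1)
    des["pursued_comparison_faster"] = [
        oculometric_decision(s, c, tie_rng) for s, c in zip(v_std, v_cmp)]

    pses = {}
    for block in ("unbiased", "biased"):
        for order in ("standard_first", "standard_second"):
            sel = des[(des.block == block) & (des.order == order)]
            for kind, col in (("psych", "report_comparison_faster"),
                              ("oculo", "pursued_comparison_faster")):
                binned = pmf.bin_trials(sel.comparison, sel[col])
                fit = pmf.fit_psychometric(binned)
                if not fit.converged:
                    return None
                o = "o1" if order == "standard_first" else "o2"
                pses[f"{kind}_{o}_{block}"] = fit.pse
    out = {"reward_order": sess.reward_order}
    for kind in ("psych", "oculo"):
        out[f"{kind}_bias"] = pmf.bias_index(
            pses[f"{kind}_o1_unbiased"], pses[f"{kind}_o2_unbiased"],
            pses[f"{kind}_o1_biased"], pses[f"{kind}_o2_biased"],
            sess.reward_order)
    out.update(pses)
    return out


def run_exp2(config: dict) -> dict:
    """Pursuit/report dissociation chain: velocity processing, oculometric
    decisions, four psychometric + four oculometric fits per participant,
    bias indices, and the group comparison."""
    seed = int(config.get("seed", 0))
    n = int(config.get("n_participants", 20))
    with_traces = bool(config.get("with_traces", True))
    base = syn.ObserverExp2(**config.get("observer", {}))
    cohort = syn.sample_cohort(base, n, seed, config.get("between"))
    part_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence(seed + 1).spawn(n)]
    fspec = FilterSpec(**config.get("filter", {}))
    overrides = config.get("overrides", {})

    rows, excluded = [], []
    for i, (obs, ps) in enumerate(zip(cohort, part_seeds)):
        sess = syn.gen_exp2_session(
            obs, syn.SessionSpec(experiment_id=2, seed=ps, overrides=overrides),
            reward_order="first" if i % 2 == 0 else "second",
            with_traces=with_traces)
        res = _analyze_exp2_participant(sess, fspec, seed=ps + 1)
        if res is None:
            excluded.append({"participant": i, "reason": "unfittable function"})
            continue
        res.update(participant=i, seed=ps,
                   true_response_bias=obs.response_bias,
                   true_perceptual_bias=obs.perceptual_bias)
        rows.append(res)
    per = pd.DataFrame(rows)
    if len(per) < 3:
        raise RuntimeError("too few fittable participants")
    group = {
        "psych_bias_vs_0": t_test(per.psych_bias, mu0=0.0, sides="greater"),
        "oculo_bias_vs_0": t_test(per.oculo_bias, mu0=0.0, sides="two-sided"),
        "psych_vs_oculo": t_test(per.psych_bias, per.oculo_bias, paired=True,
                                 sides="two-sided"),
    }
    return {"experiment": 2,
            "config": {"seed": seed, "n_participants": n,
                       "with_traces": with_traces, "overrides": overrides},
            "participants": per, "group": group,
            "excluded": excluded, "n_excluded": len(excluded)}


def run_exp3(config: dict) -> dict:
    """Ambiguity chain: distance-to-region time courses aligned to
    reversals, cluster-permutation test, and the intentional-phase
    fixation-label permutation tests."""
    seed = int(config.get("seed", 0))
    n = int(config.get("n_participants", 16))
    n_perm = int(config.get("n_perm", 1000))
    decim = int(config.get("decimate", 10))
    window = tuple(config.get("window", (-1000.0, 1000.0)))
    base = syn.ObserverExp3(**config.get("observer", {}))
    cohort = syn.sample_cohort(base, n, seed, config.get("between"))
    part_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence(seed + 1).spawn(n)]
    overrides = config.get("overrides", {})

    rows_a, rows_b = [], []
    hold_a, hold_b = [], []
    dropped_total = 0
    rel_times = None
    for obs, ps in zip(cohort, part_seeds):
        sess = syn.gen_exp3_session(obs, syn.SessionSpec(
            experiment_id=3, seed=ps, overrides=overrides))
        mats = {"a": [], "b": []}
        holds = {"a": [], "b": []}
        for trial in sess.trials:
            tr = trial.trace
            phase1 = tr.t < trial.phase_bounds[0]
            dist = distance_to_region(tr, obs.diagnostic_point_a)
            for target in ("a", "b"):
                sel = trial.reversal_to == target
                if not sel.any():
                    continue
                rel, mat, dropped = align_to_reversals(
                    tr.t[phase1], dist[phase1],
                    trial.reversal_times[sel], window)
                dropped_total += dropped
                if mat.size:
                    mats[target].append(mat)
                    rel_times = rel
            for percept, pos in trial.hold_positions.items():
                holds[percept].append(pos)
        if not (mats["a"] and mats["b"]):
            continue
        rows_a.append(np.vstack(mats["a"]).mean(axis=0)[::decim])
        rows_b.append(np.vstack(mats["b"]).mean(axis=0)[::decim])
        hold_a.append(np.mean(holds["a"], axis=0))
        hold_b.append(np.mean(holds["b"], axis=0))

    if len(rows_a) < 2:
        raise RuntimeError("too few participants with reversals in both directions")
    tc = AlignedTimecourses(times=rel_times[::decim],
                            cond_a=np.vstack(rows_a), cond_b=np.vstack(rows_b),
                            label_a="toward_a", label_b="toward_b")
    cluster = cluster_permutation(tc, n_perm=n_perm, seed=seed + 7)
    pa, pb = np.vstack(hold_a), np.vstack(hold_b)
    gaze_centroid = gaze_label_permutation(pa, pb, "centroid_distance",
                                           n_perm=n_perm, seed=seed + 8)
    gaze_region = gaze_label_permutation(
        pa, pb, "mean_region_distance_diff",
        region_point=base.diagnostic_point_a, n_perm=n_perm, seed=seed + 9)
    return {"experiment": 3,
            "config": {"seed": seed, "n_participants": n, "n_perm": n_perm,
                       "decimate": decim, "window": list(window),
                       "overrides": overrides},
            "n_participants_used": len(rows_a),
            "n_edge_reversals_dropped": dropped_total,
            "cluster": cluster, "gaze_centroid": gaze_centroid,
            "gaze_region": gaze_region}


def run_exp4(config: dict) -> dict:
    """Forced-fixation chain: per-fixation psychometric fits and PSE gap,
    plus illusion-block proportion-vs-chance tests (t and Wilcoxon)."""
    seed = int(config.get("seed", 0))
    n = int(config.get("n_participants", 24))
    base = syn.ObserverExp4(**config.get("observer", {}))
    cohort = syn.sample_cohort(base, n, seed, config.get("between"))
    part_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence(seed + 1).spawn(n)]
    overrides = config.get("overrides", {})

    rows, excluded = [], []
    for i, (obs, ps) in enumerate(zip(cohort, part_seeds)):
        sess = syn.gen_exp4_session(obs, syn.SessionSpec(
            experiment_id=4, seed=ps, overrides=overrides))
        fits = {}
        for fix in ("a", "b"):
            sel = sess.composite[sess.composite.fixation == fix]
            fits[fix] = pmf.fit_psychometric(
                pmf.bin_trials(sel.proportion, sel.report_face))
        if not (fits["a"].converged and fits["b"].converged):
            excluded.append({"participant": i, "reason": "unfittable function"})
            continue
        rows.append({
            "participant": i, "seed": ps,
            "pse_eyes": fits["a"].pse, "pse_house": fits["b"].pse,
            "pse_gap": pmf.pse_difference_exp4(fits["a"], fits["b"]),
            "true_gap": obs.pse_fix_b - obs.pse_fix_a,
            "prop_congruent": float(sess.illusion.congruent.mean()),
        })
    per = pd.DataFrame(rows)
    if len(per) < 3:
        raise RuntimeError("too few fittable participants")
    group = {
        "pse_house_vs_eyes": t_test(per.pse_house, per.pse_eyes, paired=True,
                                    sides="two-sided"),
        "illusion_congruent_vs_chance": t_test(per.prop_congruent, mu0=0.5,
                                               sides="two-sided"),
        "illusion_congruent_wilcoxon": wilcoxon_signed_rank(
            per.prop_congruent, mu0=0.5),
    }
    return {"experiment": 4,
            "config": {"seed": seed, "n_participants": n, "overrides": overrides},
            "participants": per, "group": group,
            "excluded": excluded, "n_excluded": len(excluded)}
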