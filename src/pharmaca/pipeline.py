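"""Study-level orchestration: run every stage over all mice with one seed.

The study design mirrors a within-subject pharmacology experiment: each mouse
contributes sessions in the order saline, saline, drug.  The drug session is
compared against the adjacent saline session (the second one by default) and
the two saline sessions against each other as an injection-order control.

``run_full_analysis`` executes response classification, synchrony detection,
cross-session tracking and decoding per mouse, pools neurons across mice for
the group comparisons (captions in this design report per-neuron n's), and
collects per-mouse decoder accuracies for paired tests.  Every stage draws
its randomness from a deterministic substream of the master seed, so partial
re-runs and full re-runs reproduce byte-identically.  A failing stage is
recorded in the report and the remaining stages proceed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import decoding, response, synchrony, tracking
from .dataio import AnalysisConfig, SessionData, read_session
from .synthgen import GeneratorConfig, generate_paired_sessions, generate_session
from .utils import derive_rng

log = logging.getLogger("pharmaca")


@dataclass
class MouseSessions:
    mouse_id: str
    sessions: list  # SessionData, ordered (saline, saline, drug) in the full design

    def __post_init__(self):
        for s in self.sessions:
            if s.mouse_id != self.mouse_id:
                raise ValueError(
                    f"session mouse_id {s.mouse_id!r} != {self.mouse_id!r}")

    def saline_sessions(self) -> list:
        return [s for s in self.sessions if s.treatment == "saline"]

    def drug_session(self) -> SessionData | None:
        drugs = [s for s in self.sessions if s.treatment != "saline"]
        return drugs[-1] if drugs else None

    def adjacent_saline(self, which: str = "second") -> SessionData | None:
        sal = self.saline_sessions()
        if not sal:
            return None
        return sal[-1] if which == "second" else sal[0]


@dataclass
class StudyDesign:
    mice: list = field(default_factory=list)  # list of MouseSessions


def load_design(path) -> StudyDesign:
    """Load a design YAML listing per-mouse session files in order."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    mice = []
    for m in d["mice"]:
        sessions = [read_session(s["path"]) for s in m["sessions"]]
        mice.append(MouseSessions(m["mouse_id"], sessions))
    return StudyDesign(mice)


def simulate_study(gen_config: GeneratorConfig, n_mice: int, master_seed: int):
    """Generate a synthetic study: per mouse one standalone saline session plus
    a shared-cell (saline, drug) pair.  Returns (design, truths) where truths
    maps mouse_id to the PairedStudy ground truth of its tracked pair."""
    mice, truths = [], {}
    for m in range(n_mice):
        mid = f"m{m}"
        rng = derive_rng(master_seed, mid, "simulate")
        s1, _ = generate_session(gen_config, "saline", rng, mouse_id=mid)
        pair = generate_paired_sessions(gen_config, rng=rng, mouse_id=mid)
        mice.append(MouseSessions(mid, [s1, pair.session_a, pair.session_b]))
        truths[mid] = pair
    return StudyDesign(mice), truths


def _stage(report, name, fn):
    try:
        fn()
        report["stages"][name] = "ok"
    except Exception as exc:  # stage isolation: others proceed
        log.exception("stage %s failed", name)
        report["stages"][name] = f"failed: {exc}"


def run_full_analysis(design: StudyDesign, config: AnalysisConfig):
    """Run all stages over the study.  Returns ``(report, tables)``.

    ``report`` is a JSON-serialisable summary; ``tables`` holds per-neuron,
    per-pair and per-mouse DataFrames for CSV export.
    """
    master = config.seed
    log.info("running full analysis: %d mice, master seed %d", len(design.mice), master)
    report: dict = {"seed": int(master), "n_mice": len(design.mice), "stages": {}}
    tables: dict = {}
    cls: dict = {}  # (mouse_id, role) -> (results_df, sizes_df)

    roles = {}
    for mouse in design.mice:
        roles[mouse.mouse_id] = {
            "saline_first": (mouse.saline_sessions() or [None])[0],
            "saline_adjacent": mouse.adjacent_saline(config.adjacent_saline),
            "drug": mouse.drug_session(),
        }

    def run_response():
        resp_tables = []
        for mouse in design.mice:
            for role, sess in roles[mouse.mouse_id].items():
                if sess is None or (mouse.mouse_id, role) in cls:
                    continue
                if role == "saline_first" and sess is roles[mouse.mouse_id]["saline_adjacent"]:
                    continue  # single-saline design: one table serves both roles
                rng = derive_rng(master, mouse.mouse_id, role, "response")
                df, sizes = response.classify_session(sess, config, rng)
                cls[(mouse.mouse_id, role)] = (df, sizes)
                out = df.copy()
                out.insert(0, "mouse_id", mouse.mouse_id)
                out.insert(1, "role", role)
                resp_tables.append(out)
        tables["response"] = pd.concat(resp_tables, ignore_index=True)

        def pooled(role):
            dfs = [cls[k][0] for k in cls if k[1] == role]
            szs = [cls[k][1] for k in cls if k[1] == role]
            if not dfs:
                return None, None
            return pd.concat(dfs, ignore_index=True), pd.concat(szs, ignore_index=True)

        drug_df, drug_sz = pooled("drug")
        sal_df, sal_sz = pooled("saline_adjacent")
        sal1_df, sal1_sz = pooled("saline_first")
        rep = {}
        if drug_df is not None and sal_df is not None:
            rep["drug_vs_saline"] = response.compare_groups(
                sal_df, drug_df, sal_sz, drug_sz, config)
        if sal1_df is not None and sal_df is not None:
            rep["saline_order_control"] = response.compare_groups(
                sal1_df, sal_df, sal1_sz, sal_sz, config)
        report["response"] = rep

    def run_synchrony():
        rep = {}
        pair_tables = []
        for role, treat in (("saline_adjacent", "saline"), ("drug", "drug")):
            pooled = {g: {"n_pairs_total": 0, "n_pairs_synchronous": 0}
                      for g in ("excited", "stable")}
            for mouse in design.mice:
                sess = roles[mouse.mouse_id][role]
                key = (mouse.mouse_id, role)
                if sess is None or key not in cls:
                    continue
                rng = derive_rng(master, mouse.mouse_id, role, "synchrony")
                pairs, summaries, _ = synchrony.detect_synchronous_pairs(
                    sess, cls[key][0], config, rng)
                pairs.insert(0, "mouse_id", mouse.mouse_id)
                pairs.insert(1, "role", role)
                pair_tables.append(pairs)
                for g in pooled:
                    pooled[g]["n_pairs_total"] += summaries[g]["n_pairs_total"]
                    pooled[g]["n_pairs_synchronous"] += summaries[g]["n_pairs_synchronous"]
            for g, d in pooled.items():
                d["proportion"] = (d["n_pairs_synchronous"] / d["n_pairs_total"]
                                   if d["n_pairs_total"] else np.nan)
            entry = {"groups": pooled, "excited_vs_stable": None}
            if all(pooled[g]["n_pairs_total"] > 0 for g in pooled):
                from . import stats
                table = [[pooled["excited"]["n_pairs_synchronous"],
                          pooled["excited"]["n_pairs_total"]
                          - pooled["excited"]["n_pairs_synchronous"]],
                         [pooled["stable"]["n_pairs_synchronous"],
                          pooled["stable"]["n_pairs_total"]
                          - pooled["stable"]["n_pairs_synchronous"]]]
                entry["excited_vs_stable"] = stats.asdict(stats.fisher_exact_2x2(table))
            rep[treat] = entry
        pair_tables = [t for t in pair_tables if len(t)]
        if pair_tables:
            tables["synchrony_pairs"] = pd.concat(pair_tables, ignore_index=True)
        report["synchrony"] = rep

    def run_tracking():
        all_matches = []
        pooled_labels_a, pooled_labels_b = [], []
        for mouse in design.mice:
            sal = roles[mouse.mouse_id]["saline_adjacent"]
            drug = roles[mouse.mouse_id]["drug"]
            if sal is None or drug is None:
                continue
            matches = tracking.match_cells(sal.centroids, drug.centroids,
                                           config.track_max_dist_um)
            la = cls[(mouse.mouse_id, "saline_adjacent")][0]["label"].to_numpy()
            lb = cls[(mouse.mouse_id, "drug")][0]["label"].to_numpy()
            for _, row in matches.iterrows():
                pooled_labels_a.append(la[int(row["neuron_id_a"])])
                pooled_labels_b.append(lb[int(row["neuron_id_b"])])
            matches.insert(0, "mouse_id", mouse.mouse_id)
            all_matches.append(matches)
        rep = {"n_matched": len(pooled_labels_a), "contingency": None}
        if pooled_labels_a:
            idx = np.arange(len(pooled_labels_a))
            fake_matches = pd.DataFrame(
                {"neuron_id_a": idx, "neuron_id_b": idx, "distance": 0.0})
            table, res = tracking.cross_session_contingency(
                fake_matches, pooled_labels_a, pooled_labels_b)
            if table is not None:
                from . import stats
                rep["contingency"] = {
                    "table": table.to_numpy().tolist(),
                    "test": stats.asdict(res),
                }
        if all_matches:
            tables["tracking_matches"] = pd.concat(all_matches, ignore_index=True)
        report["tracking"] = rep

    def run_decoding():
        rows = []
        for mouse in design.mice:
            sal = roles[mouse.mouse_id]["saline_adjacent"]
            drug = roles[mouse.mouse_id]["drug"]
            if sal is None or drug is None:
                continue
            res_s = cls[(mouse.mouse_id, "saline_adjacent")][0]
            res_d = cls[(mouse.mouse_id, "drug")][0]
            pool_s = decoding.decoding_pool(res_s, sal.n_neurons, config)
            pool_d = decoding.decoding_pool(res_d, drug.n_neurons, config)
            rng = derive_rng(master, mouse.mouse_id, "decoding")
            pop = decoding.matched_population_accuracy(
                sal, drug, config, rng, pool_a=pool_s, pool_b=pool_d)
            rows.append(dict(mouse_id=mouse.mouse_id, variant="population",
                             saline=pop["accuracy_a"], drug=pop["accuracy_b"],
                             n_neurons_used=pop["n_neurons_used"]))
            sn_s = decoding.single_neuron_accuracy(sal, config, rng, pool=pool_s)
            sn_d = decoding.single_neuron_accuracy(drug, config, rng, pool=pool_d)
            rows.append(dict(mouse_id=mouse.mouse_id, variant="single_neuron_mean",
                             saline=sn_s["mean_accuracy"], drug=sn_d["mean_accuracy"],
                             n_neurons_used=min(sn_s["n_neurons"], sn_d["n_neurons"])))
            for lab in ("excited", "inhibited", "stable"):
                try:
                    abl = decoding.ablation_accuracy(
                        sal, drug, res_s, res_d, lab, config, rng)
                    rows.append(dict(mouse_id=mouse.mouse_id,
                                     variant=f"minus_{lab}",
                                     saline=abl["accuracy_a"], drug=abl["accuracy_b"],
                                     n_neurons_used=abl["n_neurons_used"]))
                except ValueError as exc:
                    log.warning("mouse %s ablation %s skipped: %s",
                                mouse.mouse_id, lab, exc)
        acc = pd.DataFrame(rows)
        tables["decoding"] = acc
        rep = {"per_mouse": rows, "paired_tests": {}}
        for variant, grp in acc.groupby("variant"):
            if len(grp) >= 2:
                from . import stats
                res = decoding.compare_accuracies(grp["saline"].to_numpy(),
                                                  grp["drug"].to_numpy())
                rep["paired_tests"][variant] = stats.asdict(res)
        report["decoding"] = rep

    _stage(report, "response", run_response)
    _stage(report, "synchrony", run_synchrony)
    _stage(report, "tracking", run_tracking)
    _stage(report, "decoding", run_decoding)
    return report, tables
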