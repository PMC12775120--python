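"""Untargeted prioritization across peak-picking tools.

Implements the aggregation end of the screening workflow: matching
features across tool outputs by m/z and retention time into unified
variable indices, retaining candidates whose stability and loading
evidence agrees between at least two tools within the same aligned
component, and reporting ranked candidate lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_table import FeatureTable
from .stability import StabilityResult, _greedy_match

__all__ = [
    "ReportConfig",
    "CrossToolMatch",
    "PrioritizationResult",
    "match_features_across_tools",
    "aggregate_prioritized",
    "proportion_above_threshold",
    "write_report",
]


@dataclass
class ReportConfig:
    """Thresholds and tolerances of the prioritization/report stage.

    freq_threshold is the strict ("high") stability threshold;
    freq_threshold_moderate the lower bound of the moderate band used
    by cross-tool aggregation (narrow/abrupt spills may justify values
    down to 0.40).
    """

    top_k: int = 10
    freq_threshold: float = 0.70
    freq_threshold_moderate: float = 0.50
    p_threshold: float = 0.05
    alpha: float = 0.01
    mz_tol_ppm: float = 5.0
    rt_tol: float = 0.1
    n_components: int = 10

    def __post_init__(self):
        for name in ("freq_threshold", "freq_threshold_moderate", "p_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.mz_tol_ppm <= 0 or self.rt_tol <= 0:
            raise ValueError("matching tolerances must be > 0")


@dataclass
class CrossToolMatch:
    """Unified variable indexing across tool outputs.

    ``unified`` has one row per (unified_id, tool_id, feature_id) with
    the member's m/z and RT; a unified id groups at most one feature per
    tool, all within tolerance of the group medoid.  ``unmatched`` lists
    features without a cross-tool partner.
    """

    unified: pd.DataFrame
    unmatched: dict
    mz_tol_ppm: float
    rt_tol: float

    @property
    def n_groups(self) -> int:
        return 0 if self.unified.empty else int(self.unified["unified_id"].nunique())

    def members(self, unified_id: int) -> pd.DataFrame:
        return self.unified[self.unified["unified_id"] == unified_id]


def _ppm(mz_a: float, mz_b: float) -> float:
    return abs(mz_a - mz_b) / (0.5 * (mz_a + mz_b)) * 1e6


def match_features_across_tools(
    tables: dict,
    mz_tol_ppm: float = 5.0,
    rt_tol: float = 0.1,
) -> CrossToolMatch:
    """Greedy nearest-neighbour grouping of features across >= 2 tables.

    ``tables`` maps tool_id -> FeatureTable.  Candidate cross-tool pairs
    within both tolerances are processed in order of (m/z ppm distance,
    RT distance); two groups merge only if the merged group keeps at
    most one feature per tool and all members stay pairwise within
    tolerance, so no group ever violates the tolerance around its
    medoid.  Deterministic given the inputs.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 tables to match across tools")
    nodes = []  # (tool_id, feature_id, mz, rt)
    for tool_id, table in tables.items():
        if not isinstance(table, FeatureTable):
            raise TypeError("tables values must be FeatureTable")
        meta = table.feature_meta
        if meta["mz"].isna().any() or meta["rt"].isna().any():
            raise ValueError(f"table {tool_id!r} lacks m/z or RT metadata")
        for _, row in meta.iterrows():
            nodes.append((tool_id, row["feature_id"], float(row["mz"]), float(row["rt"])))

    tools = [n[0] for n in nodes]
    mzs = np.array([n[2] for n in nodes])
    rts = np.array([n[3] for n in nodes])
    n_nodes = len(nodes)

    # candidate cross-tool pairs within tolerance, sorted by distance
    order = np.argsort(mzs, kind="stable")
    pairs = []
    for oi, i in enumerate(order):
        for j in order[oi + 1 :]:
            if _ppm(mzs[i], mzs[j]) > mz_tol_ppm:
                break  # sorted by m/z: no further partner possible
            if tools[i] == tools[j]:
                continue
            drt = abs(rts[i] - rts[j])
            if drt > rt_tol:
                continue
            pairs.append((_ppm(mzs[i], mzs[j]), drt, int(min(i, j)), int(max(i, j))))
    pairs.sort()

    group_of = list(range(n_nodes))
    members: dict[int, list[int]] = {i: [i] for i in range(n_nodes)}

    def _can_merge(ga: int, gb: int) -> bool:
        ma, mb = members[ga], members[gb]
        tool_set = {tools[i] for i in ma}
        if any(tools[i] in tool_set for i in mb):
            return False
        for i in ma:
            for j in mb:
                if _ppm(mzs[i], mzs[j]) > mz_tol_ppm or abs(rts[i] - rts[j]) > rt_tol:
                    return False
        return True

    for _, _, i, j in pairs:
        ga, gb = group_of[i], group_of[j]
        if ga == gb:
            continue
        if not _can_merge(ga, gb):
            continue
        for m in members[gb]:
            group_of[m] = ga
        members[ga].extend(members.pop(gb))

    rows, unmatched = [], {t: [] for t in tables}
    uid = 0
    for g in sorted(members, key=lambda g: min(members[g])):
        mem = members[g]
        if len(mem) < 2:
            i = mem[0]
            unmatched[tools[i]].append(nodes[i][1])
            continue
        for i in sorted(mem):
            rows.append((uid, tools[i], nodes[i][1], mzs[i], rts[i]))
        uid += 1
    unified = pd.DataFrame(
        rows, columns=["unified_id", "tool_id", "feature_id", "mz", "rt"]
    )
    return CrossToolMatch(
        unified=unified, unmatched=unmatched, mz_tol_ppm=mz_tol_ppm, rt_tol=rt_tol
    )


# ----------------------------------------------------------------------
# aggregation
# ----------------------------------------------------------------------


@dataclass
class PrioritizationResult:
    """Consensus candidates, single-tool appendix, and raw evidence rows."""

    consensus: pd.DataFrame
    appendix: pd.DataFrame
    evidence: pd.DataFrame


def _align_tool_components(stability_per_tool: dict, match: CrossToolMatch, cfg_idx: dict):
    """Per-tool permutation aligning components to the first tool's.

    Components are matched by greedy |cosine| of reference loadings
    restricted to the unified features shared with the base tool.
    """
    tools = list(stability_per_tool)
    base = tools[0]
    perms = {base: None}
    base_stab = stability_per_tool[base]
    base_ref = base_stab.reference_models[cfg_idx[base]]
    base_ids = {f: i for i, f in enumerate(base_stab.feature_ids)}
    for tool in tools[1:]:
        stab = stability_per_tool[tool]
        ref = stab.reference_models[cfg_idx[tool]]
        ids = {f: i for i, f in enumerate(stab.feature_ids)}
        rows_b, rows_t = [], []
        for uid, grp in match.unified.groupby("unified_id"):
            by_tool = dict(zip(grp["tool_id"], grp["feature_id"]))
            if base in by_tool and tool in by_tool:
                fb, ft = by_tool[base], by_tool[tool]
                if fb in base_ids and ft in ids:
                    rows_b.append(base_ids[fb])
                    rows_t.append(ids[ft])
        if len(rows_b) >= 2:
            Bb = base_ref.loadings[rows_b, :]
            Bt = ref.loadings[rows_t, :]

            def _unit(M):
                nrm = np.linalg.norm(M, axis=0)
                nrm[nrm == 0] = 1.0
                return M / nrm

            perms[tool] = _greedy_match(_unit(Bb), _unit(Bt))
        else:
            perms[tool] = np.arange(base_ref.loadings.shape[1])
    return perms


def aggregate_prioritized(
    stability_per_tool: dict,
    rankings_per_tool: dict,
    match: CrossToolMatch,
    config: ReportConfig,
    penalty_config=None,
) -> PrioritizationResult:
    """Cross-tool consensus list of prioritized features.

    A unified feature is retained when, within the same aligned
    component, at least two tools select it with frequency above the
    moderate threshold AND at least one of those tools ranks it within
    the top-k by absolute loading.  Features whose evidence holds in a
    single tool only go to the appendix.  Candidates are sorted by
    (supporting tools desc, mean frequency desc, mean loading rank asc,
    unified id asc) so reports are byte-stable.

    ``stability_per_tool`` maps tool_id -> StabilityResult (with
    feature_ids); ``rankings_per_tool`` maps tool_id -> {component ->
    rank_loadings frame}; ``penalty_config`` picks the grid
    configuration (default: each tool's first).
    """
    if not stability_per_tool:
        raise ValueError("stability_per_tool must not be empty")
    tools = list(stability_per_tool)
    cfg_idx = {}
    for tool, stab in stability_per_tool.items():
        if stab.feature_ids is None:
            raise ValueError(f"StabilityResult of {tool!r} lacks feature_ids")
        cfg_idx[tool] = (
            stab.config_index(penalty_config) if penalty_config is not None else 0
        )
    perms = _align_tool_components(stability_per_tool, match, cfg_idx)
    A = min(
        config.n_components,
        min(s.n_components for s in stability_per_tool.values()),
    )

    ev_rows = []
    for uid, grp in match.unified.groupby("unified_id"):
        for _, row in grp.iterrows():
            tool, fid = row["tool_id"], row["feature_id"]
            if tool not in stability_per_tool:
                continue
            stab = stability_per_tool[tool]
            try:
                fi = stab.feature_ids.index(fid)
            except ValueError:
                continue
            perm = perms.get(tool)
            for a in range(A):  # a: base-tool (aligned) component, 0-based
                ta = int(perm[a]) if perm is not None else a
                freq = float(stab.freq[cfg_idx[tool], ta, fi])
                pval = (
                    float(stab.pvals[cfg_idx[tool], ta, fi])
                    if stab.pvals is not None
                    else np.nan
                )
                ranks = rankings_per_tool.get(tool, {}).get(ta + 1)
                in_top = False
                rank = np.nan
                if ranks is not None and len(ranks):
                    hit = ranks[ranks["feature_id"] == fid]
                    if len(hit):
                        rank = float(hit["rank"].iloc[0])
                        in_top = rank <= config.top_k
                ev_rows.append(
                    dict(
                        unified_id=int(uid),
                        component=a + 1,
                        tool_id=tool,
                        feature_id=fid,
                        freq=freq,
                        pval=pval,
                        rank=rank,
                        in_top_k=in_top,
                    )
                )
    evidence = pd.DataFrame.from_records(ev_rows)

    cons_rows, app_rows = [], []
    if not evidence.empty:
        for (uid, a), ev in evidence.groupby(["unified_id", "component"]):
            stable = ev[ev["freq"] > config.freq_threshold_moderate]
            if len(stable) >= 2 and stable["in_top_k"].any():
                cons_rows.append(
                    dict(
                        unified_id=int(uid),
                        component=int(a),
                        n_tools=int(len(stable)),
                        mean_freq=float(stable["freq"].mean()),
                        mean_rank=float(stable["rank"].mean())
                        if stable["rank"].notna().any()
                        else np.nan,
                        tools=",".join(sorted(stable["tool_id"])),
                        feature_ids=",".join(
                            stable.sort_values("tool_id")["feature_id"]
                        ),
                    )
                )
            elif len(stable) == 1:
                r = stable.iloc[0]
                app_rows.append(
                    dict(
                        unified_id=int(uid),
                        component=int(a),
                        tool_id=r["tool_id"],
                        feature_id=r["feature_id"],
                        freq=float(r["freq"]),
                        in_top_k=bool(r["in_top_k"]),
                    )
                )
    consensus = pd.DataFrame.from_records(
        cons_rows,
        columns=[
            "unified_id",
            "component",
            "n_tools",
            "mean_freq",
            "mean_rank",
            "tools",
            "feature_ids",
        ],
    )
    if len(consensus):
        consensus = consensus.sort_values(
            ["n_tools", "mean_freq", "mean_rank", "unified_id", "component"],
            ascending=[False, False, True, True, True],
            na_position="last",
        ).reset_index(drop=True)
    appendix = pd.DataFrame.from_records(
        app_rows,
        columns=["unified_id", "component", "tool_id", "feature_id", "freq", "in_top_k"],
    )
    return PrioritizationResult(consensus=consensus, appendix=appendix, evidence=evidence)


def proportion_above_threshold(
    stability: StabilityResult,
    feature,
    component_range=None,
    threshold: float = 0.70,
) -> float:
    """Fraction of grid configurations selecting a feature stably.

    A configuration counts when the feature's selection frequency
    exceeds ``threshold`` in at least one of the stated components
    (1-based; default: all).
    """
    if isinstance(feature, str):
        if stability.feature_ids is None:
            raise ValueError("StabilityResult lacks feature_ids")
        fi = stability.feature_ids.index(feature)
    else:
        fi = int(feature)
    comps = (
        np.asarray(list(component_range), dtype=int) - 1
        if component_range is not None
        else np.arange(stability.n_components)
    )
    hits = (stability.freq[:, comps, fi] > threshold).any(axis=1)
    return float(hits.mean())


# ----------------------------------------------------------------------
# reporting
# ----------------------------------------------------------------------


def write_report(
    path,
    model,
    model_report: dict,
    stability: StabilityResult | None = None,
    prioritization: PrioritizationResult | None = None,
    metadata: dict | None = None,
) -> None:
    """Plain-markdown run summary: per-component top-K tables, control
    limits with flagged time points, and (optionally) the cross-tool
    consensus list."""
    lines = ["# SBS-SPCA run report", ""]
    if metadata:
        lines.append("## Run metadata")
        for k, v in metadata.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    lines.append("## Final model")
    lines.append(
        f"- sparsity {model.config.sparsity}, ridge {model.config.ridge}, "
        f"{model.n_components} components, converged={model.converged}"
    )
    lines.append(
        "- adjusted explained variance (%): "
        + ", ".join(f"PC{a + 1}: {v:.2f}" for a, v in enumerate(model.adj_var))
        + f" (total {model.total_adj_var:.2f}%)"
    )
    lines.append("")
    for a, ranks in model_report.get("rankings", {}).items():
        lines.append(f"### PC{a} top features by |loading|")
        if len(ranks) == 0:
            lines.append("(no non-zero loadings)")
        else:
            lines.append("```\n" + ranks.to_string(index=False) + "\n```")
        lo, hi = model_report["control_limits"][a]
        flagged = model_report["flagged_time_points"][a]
        lines.append(
            f"- control limits [{lo:.3f}, {hi:.3f}]; flagged time points: "
            + (", ".join(map(str, flagged)) if flagged else "none")
        )
        lines.append("")
    if stability is not None:
        lines.append("## Stability selection")
        md = stability.metadata()
        lines.append(
            f"- {len(md['configs'])} configurations x {md['n_reps']} replicates; "
            f"alignment: {md['alignment']}"
        )
        lines.append("")
    if prioritization is not None:
        lines.append("## Cross-tool consensus candidates")
        if len(prioritization.consensus) == 0:
            lines.append("(none)")
        else:
            lines.append(
                "```\n" + prioritization.consensus.to_string(index=False) + "\n```"
            )
        lines.append("")
        lines.append(
            f"(single-tool appendix: {len(prioritization.appendix)} entries)"
        )
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
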