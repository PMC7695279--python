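"""Readers, writers, configuration and end-to-end orchestration.

Campaign tables are delimited text with one row per sampling date per reactor;
OTU tables round-trip through TSV (otu id, lineage, per-sample counts) and
BIOM v1.0 JSON.  ``run_pipeline`` chains simulate -> performance -> qPCR ->
community -> network and writes a machine-readable run log with every seed and
iteration count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as cm
from . import massbalance as mb
from . import network as nw
from . import qpcr as qp
from . import simulate as sim

logger = logging.getLogger(__name__)

CAMPAIGN_COLUMNS = {
    "t_days": "days since campaign start (or ISO date)",
    "reactor_id": "reactor label (e.g. PBR, RWP)",
    "pH": "reactor pH",
    "T_r": "reactor temperature, C",
    "HRT_d": "mean hydraulic retention time over the preceding interval, days",
}
_ANALYTE_COLS = {f"{a}_in": a for a in mb.ANALYTES} | {f"{a}_out": a for a in mb.ANALYTES}
_OPTIONAL = ("DO", "turbidity", "OD680")


@dataclass
class CampaignConfig:
    """Configuration of a full pipeline run (YAML-serialisable).

    Thresholds, alpha levels, window length and iteration counts default to
    the campaign's statistical conventions: 1% eukaryote species / 10%
    bacterial genus dominance thresholds, alpha 0.05, 7-day covariate windows,
    999 permutations for the community-shift test and 1000 iterations for the
    network permutation/bootstrap support.
    """

    schema_version: int = 1
    scenario: str = "pbr"
    seed: int = 0
    euk_threshold: float = 0.01
    bac_threshold: float = 0.10
    network_threshold: float = 0.01
    alpha: float = 0.05
    env_window_days: float = 7.0
    simprof_permutations: int = 999
    network_iterations: int = 1000
    min_methods: int = 2
    noise_cv: float = 0.05
    read_depth: int = 20000
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("euk_threshold", "bac_threshold", "network_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.simprof_permutations < 100 or self.network_iterations < 100:
            raise ValueError("iteration counts must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CampaignConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _parse_times(col: pd.Series) -> np.ndarray:
    """Day offsets from a t_days column that may hold numbers or ISO dates."""
    try:
        return col.astype(float).values
    except (ValueError, TypeError):
        dates = pd.to_datetime(col, format="ISO8601")
        return (dates - dates.min()).dt.total_seconds().values / 86400.0


def read_campaign(path: str | Path, reactor_id: str | None = None) -> list[mb.SampleEvent]:
    """Read a delimited campaign table into typed sampling events.

    Mandatory columns: t_days (numeric day offsets or ISO dates), reactor_id,
    pH, T_r, HRT_d, and any subset of ``<analyte>_in`` / ``<analyte>_out``.
    Rows must be strictly increasing in time within a reactor; malformed rows
    raise with their line number.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"t_days", "reactor_id", "pH", "T_r"} - set(df.columns)
    if missing:
        raise ValueError(f"missing mandatory columns: {sorted(missing)}")
    if reactor_id is not None:
        df = df[df["reactor_id"] == reactor_id]
        if df.empty:
            raise ValueError(f"no rows for reactor {reactor_id!r}")
    df = df.reset_index(drop=True)
    times = _parse_times(df["t_days"])
    events: list[mb.SampleEvent] = []
    prev = -np.inf
    for i, row in df.iterrows():
        t = float(times[i])
        if t <= prev:
            raise ValueError(f"line {i + 2}: non-increasing sampling time {row['t_days']!r}")
        prev = t
        a_in = {a: float(row[c]) for c, a in _ANALYTE_COLS.items()
                if c.endswith("_in") and c in df.columns and pd.notna(row[c])}
        a_out = {a: float(row[c]) for c, a in _ANALYTE_COLS.items()
                 if c.endswith("_out") and c in df.columns and pd.notna(row[c])}
        try:
            events.append(
                mb.SampleEvent(
                    t=t, analytes_in=a_in, analytes_out=a_out,
                    pH=float(row["pH"]), T_r=float(row["T_r"]),
                    HRT=float(row["HRT_d"]) if "HRT_d" in df.columns and pd.notna(row.get("HRT_d")) else None,
                    **{k: (float(row[k]) if k in df.columns and pd.notna(row.get(k)) else None)
                       for k in _OPTIONAL},
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {i + 2}: {exc}") from exc
    return events


def write_campaign(events: list[mb.SampleEvent], path: str | Path, reactor_id: str = "R") -> None:
    rows = []
    for e in events:
        row = {"t_days": e.t, "reactor_id": reactor_id, "pH": e.pH, "T_r": e.T_r,
               "HRT_d": e.HRT, "DO": e.DO, "turbidity": e.turbidity, "OD680": e.OD680}
        row.update({f"{a}_in": v for a, v in e.analytes_in.items()})
        row.update({f"{a}_out": v for a, v in e.analytes_out.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_otu_table(path: str | Path, format: str = "tsv") -> cm.OtuTable:
    """Read an OTU table from TSV (otu_id, lineage, sample columns) or BIOM-JSON."""
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"otu_id": str})
        if "otu_id" not in df.columns or "lineage" not in df.columns:
            raise ValueError("TSV OTU table needs 'otu_id' and 'lineage' columns")
        df = df.set_index("otu_id")
        lineages = df.pop("lineage").fillna("k__unclassified")
        marker = "16S"
        if "marker" in df.columns:
            marker = str(df["marker"].iloc[0])
            df = df.drop(columns=["marker"])
        domains = None
        if "domain" in df.columns:
            domains = df.pop("domain")
        counts = df.astype(float)
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        counts = counts.T.astype(int)
        counts.columns.name = None
        counts.index.name = None
        return cm.OtuTable(counts=counts, lineages=lineages,
                           marker=marker, domains=domains)
    if format == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        dense = np.zeros((len(otu_ids), len(sample_ids)))
        if doc.get("matrix_type") == "sparse":
            for r, c, v in doc["data"]:
                dense[r, c] = v
        else:
            dense = np.asarray(doc["data"], dtype=float)
        lineages = pd.Series(
            {
                r["id"]: ";".join(r.get("metadata", {}).get("taxonomy", []))
                or "k__unclassified"
                for r in doc["rows"]
            }
        )
        marker = (doc.get("comment") or "16S").strip() or "16S"
        counts = pd.DataFrame(dense.T, index=sample_ids, columns=otu_ids).astype(int)
        return cm.OtuTable(counts=counts, lineages=lineages, marker=marker)
    raise ValueError(f"unknown format {format!r}; use 'tsv' or 'biom'")


def write_otu_table(table: cm.OtuTable, path: str | Path, format: str = "tsv") -> None:
    """Write an OTU table; read_otu_table(write_otu_table(x)) == x."""
    if format == "tsv":
        df = table.counts.T.copy()
        df.insert(0, "lineage", table.lineages)
        df.insert(1, "domain", table.domains)
        df.insert(2, "marker", table.marker)
        df.index.name = "otu_id"
        df.to_csv(path, sep="\t")
        return
    if format == "biom":
        counts = table.counts.T  # rows = OTUs in BIOM
        data = [
            [int(r), int(c), float(counts.iat[r, c])]
            for r in range(counts.shape[0])
            for c in range(counts.shape[1])
            if counts.iat[r, c] != 0
        ]
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "phycodyn",
            "date": "",
            "comment": table.marker,
            "matrix_type": "sparse",
            "matrix_element_type": "float",
            "shape": list(counts.shape),
            "rows": [
                {"id": str(o), "metadata": {"taxonomy": str(table.lineages[o]).split(";")}}
                for o in counts.index
            ],
            "columns": [{"id": str(s), "metadata": None} for s in counts.columns],
            "data": data,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return
    raise ValueError(f"unknown format {format!r}")


def write_graphml(net: nw.BipartiteNetwork, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(net.graph, path)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def simulate_scenario(config: CampaignConfig) -> dict:
    """Generate one full synthetic campaign under the configured scenario."""
    seed = config.seed
    forcing = sim.generate_forcing(seed=seed)
    params = sim.scenario_params(config.scenario)
    truth = sim.simulate_reactor(params, forcing, seed=seed)
    niches = sim.default_niches()
    comps = sim.simulate_community(niches, forcing, truth)
    sampled = sim.sample_campaign(
        truth, comps, niches, noise_cv=config.noise_cv,
        read_depth=config.read_depth, seed=seed + 1,
    )
    return {"forcing": forcing, "truth": truth, "niches": niches,
            "compositions": comps, "sampled": sampled}


def run_pipeline(config: CampaignConfig, out_dir: str | Path) -> dict:
    """Execute simulate -> perf -> qpcr -> community -> network end to end.

    Writes campaign.csv, otu_16S.tsv / otu_ITS.tsv, rates.csv, qpcr.csv,
    cluster JSON + newick, the network edge list / GraphML, the index report
    and a run log recording every seed and iteration count.  A stage failure
    aborts with the stage named; artifacts written so far are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config)}
    stage = "simulate"
    try:
        bundle = simulate_scenario(config)
        sampled = bundle["sampled"]
        events = sampled["events"]
        write_campaign(events, out / "campaign.csv", reactor_id=config.scenario.upper())
        for marker, table in sampled["otu_tables"].items():
            write_otu_table(table, out / f"otu_{marker}.tsv")

        stage = "perf"
        rates = {a: mb.volumetric_rate(events, a) for a in mb.ANALYTES}
        rate_rows = [
            {"analyte": a, "t_start": r.t_start, "t_end": r.t_end, "pr": r.pr, "rr": r.rr}
            for a, lst in rates.items() for r in lst
        ]
        pd.DataFrame(rate_rows).to_csv(out / "rates.csv", index=False)
        etas = [mb.removal_efficiency(e, "NH4-N").eta for e in events]
        pr_no2 = np.array([r.pr for r in rates["NO2-N"]])
        pr_no3 = np.array([r.pr for r in rates["NO3-N"]])
        report["perf"] = {
            "rrTAN_mean": -float(np.mean([r.pr for r in rates["NH4-N"]])),
            "etaTAN_mean": float(np.mean(etas)),
            "prNOx_mean": float(np.mean(mb.ammonium_oxidation_rate(pr_no2, pr_no3))),
            "prVSS_mean": float(np.mean([r.pr for r in rates["VSS"]])),
        }

        stage = "qpcr"
        qdata = sim.generate_qpcr_dataset(n_samples=len(events), seed=config.seed + 2)
        qrows = []
        for target in ("16S", "amoA"):
            std = qdata["standards"].query("target == @target")
            curve = qp.fit_standard_curve(
                qp.StandardSeries(target, std["log10_copies"].values, std["ct"].values)
            )
            smp = qdata["samples"].query("target == @target")
            for _, row in smp.iterrows():
                copies, cv = qp.quantify(curve, row[["ct_rep1", "ct_rep2", "ct_rep3"]].values)
                cells = qp.copies_to_cells(copies, target)
                qrows.append({"sample_id": row["sample_id"], "target": target,
                              "copies": copies, "cv": cv, "cells": cells.cells_per_gvss,
                              "efficiency": curve.efficiency})
        pd.DataFrame(qrows).to_csv(out / "qpcr.csv", index=False)
        report["qpcr"] = {"n_quantified": len(qrows)}

        stage = "community"
        tables = sampled["otu_tables"]
        euk_prof = cm.relative_abundance(tables["ITS"], rank="species",
                                         threshold=config.euk_threshold)
        bac_prof = cm.relative_abundance(tables["16S"], rank="genus",
                                         threshold=config.bac_threshold)
        results_cluster = {}
        for label, prof in (("eukaryote", euk_prof), ("bacteria", bac_prof)):
            bc = cm.bray_curtis_matrix(prof)
            bc.to_csv(out / f"braycurtis_{label}.csv")
            res = cm.cluster_simprof(bc, prof, n_perm=config.simprof_permutations,
                                     alpha=config.alpha, seed=config.seed + 3)
            (out / f"dendrogram_{label}.nwk").write_text(
                cm.dendrogram_newick(res.linkage_matrix, [str(s) for s in res.sample_ids])
            )
            results_cluster[label] = {
                "n_groups": len(res.groups),
                "groups": [list(map(str, g)) for g in res.groups],
            }
        with open(out / "clusters.json", "w") as fh:
            json.dump(results_cluster, fh, indent=2, default=_json_default)
        daily = pd.DataFrame(
            {"irradiance": bundle["forcing"].irradiance,
             "temperature": bundle["forcing"].temperature},
            index=bundle["forcing"].days,
        )
        env, _ = cm.env_window_means(daily, sampled["schedule"],
                                     window=config.env_window_days)
        env.index = euk_prof.data.index
        screen = cm.kendall_screen(euk_prof, env, alpha=config.alpha)
        screen.tau.to_csv(out / "kendall_tau.csv")
        screen.p.to_csv(out / "kendall_p.csv")
        report["community"] = {
            **{k: v["n_groups"] for k, v in
               (("euk_groups", results_cluster["eukaryote"]),
                ("bac_groups", results_cluster["bacteria"]))},
            "n_significant_correlations": int(screen.significant.values.sum()),
        }

        stage = "network"
        euk_net = cm.relative_abundance(tables["ITS"], rank="otu",
                                        threshold=config.network_threshold)
        bac_net = cm.relative_abundance(tables["16S"], rank="otu",
                                        threshold=config.network_threshold)
        cands = nw.score_edges(bac_net.data, euk_net.data)
        cands = nw.reboot_significance(cands, n_iter=config.network_iterations,
                                       seed=config.seed + 4)
        net = nw.build_network(cands, min_methods=config.min_methods, alpha=config.alpha)
        nw.edge_list(net).to_csv(out / "edges.csv", index=False)
        write_graphml(net, out / "network.graphml")
        idx = nw.network_indices(net) if net.graph.number_of_edges() else None
        report["network"] = asdict(idx) if idx else {"interaction": 0}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["run_log"] = {
        "seeds": {"simulate": config.seed, "sampling": config.seed + 1,
                  "qpcr": config.seed + 2, "simprof": config.seed + 3,
                  "network": config.seed + 4},
        "simprof_permutations": config.simprof_permutations,
        "network_iterations": config.network_iterations,
        "thresholds": {"eukaryote": config.euk_threshold, "bacteria": config.bac_threshold,
                       "network": config.network_threshold},
        "alpha": config.alpha,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report
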