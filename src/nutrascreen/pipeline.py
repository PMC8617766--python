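"""Pipeline orchestration: configuration validation and staged execution.

``run_pipeline`` wires the stages together — replicate summarization,
composite scoring, metabolite profiling, candidate screening and
significance reporting — executing whichever subset the configuration
provides inputs for.  A stage failure is recorded and skips its
dependents; independent stages continue.  All randomness flows from the
config seed, so a fixed config re-run is byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets, profiling, scoring, screening, stats
from .assay import AssayPanel, summarize_replicates
from .errors import ConfigError
from .scoring import AHCI_PARAMETERS, OGRCI_PARAMETERS, IndexConfig

log = logging.getLogger("nutrascreen")

_ND_POLICIES = {"exclude", "zero"}
_ROUNDING = {"nearest", "floor"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Path fields may be None (stage skipped) or the sentinel ``"bundled"``
    to use the packaged reference tables.
    """

    panel: str | None = "bundled"
    readouts: str | None = None
    metabolites: str | None = "bundled"
    descriptors: str | None = "bundled"
    energies: str | None = "bundled"
    interactions: str | None = "bundled"
    out_dir: str = "results"
    seed: int = 0
    alpha: float = 0.05
    nd_policy: str = "exclude"
    rounding: str = "nearest"
    lead_threshold: float = -6.0
    min_bioavailability: float = 0.55
    shortlist_size: int | None = 10
    top_n_metabolites: int = 25


@dataclass
class RunLog:
    """Timestamped stage records and warnings for one pipeline run."""

    records: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)

    def stage(self, name: str, status: str, detail: str = "") -> None:
        self.records.append(
            {
                "stage": name,
                "status": status,
                "detail": detail,
                "time": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            }
        )
        log.info("stage %s: %s %s", name, status, detail)

    def warn(self, context: str, message: str) -> None:
        self.warnings.append({"context": context, "message": message})
        log.warning("%s: %s", context, message)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config_echo,
                "stages": [
                    {k: v for k, v in rec.items() if k != "time"} for rec in self.records
                ],
                "warnings": self.warnings,
            },
            indent=2,
            ensure_ascii=False,
        )


def validate_config(raw: dict) -> PipelineConfig:
    """Validate a raw configuration mapping, aggregating all errors.

    Unknown keys, out-of-vocabulary tokens, out-of-range thresholds and
    missing referenced paths are all collected before raising a single
    :class:`ConfigError`; a valid config is returned with defaults
    injected explicitly.
    """
    errors = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    for key in sorted(unknown):
        errors.append(f"unknown config key {key!r}")
    merged = {k: v for k, v in raw.items() if k in known}
    cfg = PipelineConfig(**merged)
    if cfg.nd_policy not in _ND_POLICIES:
        errors.append(
            f"nd_policy {cfg.nd_policy!r} not in {sorted(_ND_POLICIES)}"
        )
    if cfg.rounding not in _ROUNDING:
        errors.append(f"rounding {cfg.rounding!r} not in {sorted(_ROUNDING)}")
    if not (0 < cfg.alpha < 1):
        errors.append(f"alpha {cfg.alpha} outside (0, 1)")
    if cfg.lead_threshold > 0:
        errors.append(f"lead_threshold {cfg.lead_threshold} must be <= 0 kcal/mol")
    if cfg.min_bioavailability not in {0.11, 0.17, 0.55, 0.56, 0.85}:
        errors.append(
            f"min_bioavailability {cfg.min_bioavailability} not an Abbott score"
        )
    if cfg.top_n_metabolites < 2:
        errors.append("top_n_metabolites must be >= 2")
    for name in ("panel", "readouts", "metabolites", "descriptors", "energies", "interactions"):
        value = getattr(cfg, name)
        if value not in (None, "bundled") and not Path(value).exists():
            errors.append(f"{name} path {value!r} does not exist")
    if errors:
        raise ConfigError(errors)
    return cfg


def _write_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, index=kwargs.pop("index", False), float_format="%.6g", **kwargs)


def run_pipeline(config: PipelineConfig) -> RunLog:
    """Execute all configured stages, writing the report bundle to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runlog = RunLog(config_echo=dataclasses.asdict(config))

    # ---- stage: panel ------------------------------------------------------
    panel: AssayPanel | None = None
    try:
        if config.readouts:
            raw = pd.read_csv(config.readouts)
            panel = summarize_replicates(raw)
        elif config.panel == "bundled":
            panel = datasets.load_study_panel()
        elif config.panel:
            panel = AssayPanel.from_csv(config.panel)
        if panel is not None:
            panel.to_csv(out / "panel.csv")
            runlog.stage("panel", "ok", f"{len(panel.data)} rows")
        else:
            runlog.stage("panel", "skipped", "no panel or readouts configured")
    except Exception as exc:  # stage isolation: record and continue
        runlog.stage("panel", "failed", str(exc))
        panel = None

    # ---- stage: scoring ----------------------------------------------------
    if panel is not None:
        try:
            ahci_cfg = IndexConfig(
                parameters=AHCI_PARAMETERS,
                nd_policy=config.nd_policy,
                rounding=config.rounding,
            )
            ogrci_cfg = IndexConfig(
                parameters=OGRCI_PARAMETERS,
                nd_policy=config.nd_policy,
                rounding=config.rounding,
            )
            scores = scoring.score_panel(panel, ahci_cfg, ogrci_cfg)
            ranking = scoring.rank_samples(scores)
            records = []
            for sample in scores.overall.index:
                for ep, idx in scores.indices.loc[sample].items():
                    ref_val, ref_holder = scores.reference_values[ep]
                    records.append(
                        {
                            "sample_id": sample,
                            "endpoint_id": ep,
                            "index": round(idx, 2) if pd.notna(idx) else "ND",
                            "ahci": scores.ahci[sample],
                            "ogrci": scores.ogrci[sample],
                            "overall": scores.overall[sample],
                            "reference_value": ref_val,
                            "reference_holder": ref_holder,
                        }
                    )
                    if pd.isna(idx):
                        runlog.warn(
                            f"({sample}, {ep})",
                            f"ND cell handled per nd_policy={config.nd_policy}",
                        )
            _write_csv(pd.DataFrame(records), out / "scores.csv")
            _write_csv(ranking, out / "ranking.csv")
            runlog.stage("scoring", "ok", f"{len(scores.overall)} samples scored")
        except Exception as exc:
            runlog.stage("scoring", "failed", str(exc))
    else:
        runlog.stage("scoring", "skipped", "no panel available")

    # ---- stage: stats ------------------------------------------------------
    if panel is not None:
        try:
            rng_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % 2**31)
            letters = _panel_letters(panel, config.alpha, rng_seed)
            _write_csv(letters, out / "letters.csv")
            means = panel.data[~panel.data["nd_flag"]]
            wide = means.pivot_table(index="sample_id", columns="endpoint_id", values="mean")
            if "role" in panel.data.columns:
                sample_ids = panel.samples(role="sample")
                wide = wide.loc[[s for s in wide.index if s in sample_ids]]
            corr_targets = [c for c in ("dpph_pct", "frap", "teac", "ages_pct") if c in wide.columns]
            if "tp" in wide.columns and corr_targets:
                corr = stats.correlation_table(wide, "tp", corr_targets)
                _write_csv(corr, out / "correlations.csv")
            runlog.stage("stats", "ok")
        except Exception as exc:
            runlog.stage("stats", "failed", str(exc))
    else:
        runlog.stage("stats", "skipped", "no panel available")

    # ---- stage: profiling --------------------------------------------------
    try:
        if config.metabolites == "bundled":
            met = datasets.load_metabolites()
        elif config.metabolites:
            met = pd.read_csv(config.metabolites)
        else:
            met = None
        if met is None:
            runlog.stage("profiling", "skipped", "no metabolite table configured")
        else:
            class_pct, class_counts, sub_counts = profiling.class_composition(met)
            comp = pd.DataFrame(
                {
                    "compound_class": class_pct.index,
                    "count": class_counts.reindex(class_pct.index).values,
                    "percent": class_pct.values,
                }
            )
            _write_csv(comp, out / "composition.csv")
            summary = profiling.genotype_presence_summary(met)
            abund_cols = [c for c in met.columns if c.startswith("abund_")]
            if abund_cols:
                mat = profiling.AbundanceMatrix(
                    met.set_index("name")[abund_cols].rename(
                        columns=lambda c: c[len("abund_"):]
                    )
                )
                quantified = profiling.AbundanceMatrix(
                    mat.data[(mat.data > 0).all(axis=1)], mat.normalization
                )
                n_top = min(config.top_n_metabolites, len(quantified.data))
                top = profiling.select_top_n(quantified, n_top)
                clusters = profiling.ward_cluster(top, axis="compounds")
                pca_res = profiling.pca(quantified)
                with open(out / "clusters.json", "w") as fh:
                    json.dump(
                        {"merges": clusters.merges, "leaf_order": clusters.leaf_order},
                        fh,
                        indent=2,
                        ensure_ascii=False,
                    )
                _write_csv(pca_res.scores.round(6), out / "pca_scores.csv", index=True)
                _write_csv(pca_res.loadings.round(6), out / "pca_loadings.csv", index=True)
            with open(out / "presence_summary.json", "w") as fh:
                json.dump(
                    {
                        "counts": summary.counts,
                        "unique": summary.unique,
                        "core_size": len(summary.core),
                    },
                    fh,
                    indent=2,
                    ensure_ascii=False,
                )
            runlog.stage("profiling", "ok", f"{len(met)} metabolites")
    except Exception as exc:
        runlog.stage("profiling", "failed", str(exc))

    # ---- stage: screening --------------------------------------------------
    try:
        if config.descriptors == "bundled":
            descs, abundance = datasets.load_descriptors()
        elif config.descriptors:
            df = pd.read_csv(config.descriptors)
            descs = [
                screening.MoleculeDescriptors(
                    compound=r["compound"], mw=r["mw"], logp=r["logp"],
                    hbd=int(r["hbd"]), hba=int(r["hba"]), tpsa=r["tpsa"],
                    wlogp=r.get("wlogp", r["logp"]),
                    charge_class=r.get("charge_class", "neutral"),
                )
                for _, r in df.iterrows()
            ]
            abundance = (
                dict(zip(df["compound"], df["abundance"]))
                if "abundance" in df.columns
                else None
            )
        else:
            descs = None
        if descs is None:
            runlog.stage("screening", "skipped", "no descriptor table configured")
        else:
            verdicts, shortlist = screening.screen_candidates(
                descs,
                min_bioavailability=config.min_bioavailability,
                abundance=abundance,
                top_n=config.shortlist_size,
            )
            _write_csv(
                pd.DataFrame(
                    [
                        {
                            "compound": v.compound,
                            "lipinski_pass": v.lipinski_pass,
                            "violations": ";".join(v.violations),
                            "gi_absorption": v.gi_absorption,
                            "bbb_permeant": v.bbb_permeant,
                            "bioavailability_score": v.bioavailability_score,
                            "shortlisted": v.shortlisted,
                        }
                        for v in verdicts
                    ]
                ),
                out / "screen.csv",
            )
            runlog.stage("screening", "ok", f"shortlist {len(shortlist)}")
    except Exception as exc:
        runlog.stage("screening", "failed", str(exc))

    # ---- stage: lead triage ------------------------------------------------
    try:
        if config.energies == "bundled":
            energies = datasets.load_binding_energies()
        elif config.energies:
            energies = pd.read_csv(config.energies).set_index("compound")
        else:
            energies = None
        if energies is None:
            runlog.stage("leads", "skipped", "no energies table configured")
        else:
            leads = screening.select_leads(energies, threshold=config.lead_threshold)
            best = {
                t: screening.best_binder(energies, t) for t in energies.columns
            }
            _write_csv(
                pd.DataFrame(
                    {
                        "compound": leads,
                        "rule": [
                            f"energy <= {config.lead_threshold} kcal/mol for all targets"
                        ]
                        * len(leads),
                    }
                ),
                out / "leads.csv",
            )
            _write_csv(
                pd.DataFrame(
                    [
                        {"target": t, "compound": c, "energy": e, "tied": tie}
                        for t, (c, e, tie) in best.items()
                    ]
                ),
                out / "best_binders.csv",
            )
            if config.interactions:
                inter = (
                    datasets.load_interactions()
                    if config.interactions == "bundled"
                    else pd.read_csv(config.interactions)
                )
                records = []
                for _, row in inter.iterrows():
                    records.extend(
                        screening.parse_interactions(
                            row["raw_text"], row["compound"], row["target"]
                        )
                    )
                _write_csv(
                    pd.DataFrame(
                        [
                            {
                                "compound": r.compound,
                                "target": r.target,
                                "residue": r.residue,
                                "bond_type": r.bond_type,
                            }
                            for r in records
                        ]
                    ),
                    out / "interactions_parsed.csv",
                )
            runlog.stage("leads", "ok", f"{len(leads)} leads")
    except Exception as exc:
        runlog.stage("leads", "failed", str(exc))

    with open(out / "run_log.json", "w") as fh:
        fh.write(runlog.to_json())
    return runlog


def _panel_letters(panel: AssayPanel, alpha: float, seed: int) -> pd.DataFrame:
    """Compact-letter annotation per endpoint from simulated replicates.

    The bundled panel stores only mean/SD/n, so replicates are drawn from
    Normal(mean, SD) with the run seed before ANOVA + Tukey; endpoints
    whose direction is lower-is-better assign 'a' to the smallest mean.
    """
    from .synth import GeneratorSpec, gen_assay_panel

    lower_better = {"amylase_ic50", "glucosidase_ic50", "dppiv_ic50", "ptp1b_ic50"}
    rows = []
    for k, ep in enumerate(panel.endpoints()):
        sub = panel.data[(panel.data["endpoint_id"] == ep) & (~panel.data["nd_flag"])]
        if sub["sample_id"].nunique() < 2 or (sub["n"] < 2).any():
            continue
        reps = gen_assay_panel(
            sub.rename(columns={"mean": "mean"}),
            GeneratorSpec(seed=seed + k, n_replicates=int(sub["n"].min())),
        )
        groups = [
            stats.ReplicateGroup(s, g["value"].astype(float).to_numpy())
            for s, g in reps.groupby("sample_id", sort=False)
        ]
        direction = "lower_better" if ep in lower_better else "higher_better"
        letters = stats.letters_for_endpoint(groups, alpha=alpha, direction=direction)
        for sample, letter in letters.items():
            rows.append({"sample_id": sample, "endpoint_id": ep, "letter": letter})
    return pd.DataFrame(rows)
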