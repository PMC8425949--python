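"""End-to-end run configuration and report assembly.

`run_pipeline` ties the stages together: backbone loading, page scanning,
shipment classification, CITES/IUCN/literature ingestion, five-source
merging, and the temporal analyses, writing one report bundle (CSV/JSON
tables plus a plain-text log with per-stage record counts).  Runs are
deterministic given inputs + config, and every report carries the config
hash so outputs are traceable to the exact configuration that produced
them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import external_sources, integrate, lemis, taxonomy, temporal, webscan
from .external_sources import EvidenceRecord

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("tradeweave")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Paths and knobs for one pipeline run.

    Any input path left as None disables its stage (the merge then spans the
    remaining sources); a configured path that does not exist aborts with
    the stage name.
    """

    backbone: str
    sites: str | None = None
    pages: str | None = None
    shipments: str | None = None
    keyword_table: str | None = None
    cites_checklist: str | None = None
    gross_imports: str | None = None
    narratives: str | None = None
    literature: str | None = None
    occurrence: str | None = None
    out_dir: str = "tradeweave_out"
    snapshot_year: int = 2020
    cutoff_year: int = 1999
    rounding_mode: str = "round"
    backbone_columns: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _require(path: str | None, stage: str) -> Path:
    if path is None:
        raise PipelineError(f"stage {stage}: no input path configured")
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"stage {stage}: missing input {p}")
    return p


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every configured stage and write the report bundle.

    Returns the report as a dict (also written under ``config.out_dir``):
    species profiles, source intersections, shipment summaries, yearly
    series, trend fit, lag summary and national tables, plus per-stage
    record counts and the config hash.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    report: dict[str, Any] = {"config_hash": config.config_hash()}

    # stage: taxonomy
    backbone_path = _require(config.backbone, "taxonomy")
    try:
        concepts = taxonomy.load_backbone(backbone_path, columns=config.backbone_columns or None)
        index = taxonomy.build_keyword_index(concepts)
    except taxonomy.BackboneError as exc:
        raise PipelineError(f"stage taxonomy: {exc}") from exc
    counts["backbone_species"] = len(concepts)
    counts["keywords"] = index.n_keywords

    evidence: dict[str, list[EvidenceRecord]] = {}
    detections: list[webscan.DetectionRecord] = []

    # stage: webscan
    if config.pages is not None:
        pages_dir = _require(config.pages, "webscan")
        pages = webscan.load_pages(pages_dir)
        lang_of: dict[str, str] = {}
        if config.sites is not None:
            sites = webscan.load_site_configs(_require(config.sites, "webscan"))
            lang_of = {s.site_id: s.language for s in sites}
        detections = webscan.scan_pages(pages, index, lang_of)
        counts["pages"] = len(pages)
        counts["detections"] = len(detections)
        webscan.detections_to_frame(detections).to_csv(out_dir / "detections.csv", index=False)
        report["language_summary"] = webscan.language_summary(detections).to_dict("records")
        evidence["online"] = [
            EvidenceRecord(d.accepted_name, "online", frozenset({"pet"}), d.year)
            for d in detections
        ]

    # stage: lemis
    if config.shipments is not None:
        ship_path = _require(config.shipments, "lemis")
        records = lemis.load_shipments(ship_path)
        units = lemis.filter_individual_units(records)
        counts["shipments"] = len(records)
        counts["shipments_individual_units"] = len(units)
        table = (
            lemis.load_keyword_table(_require(config.keyword_table, "lemis"))
            if config.keyword_table
            else lemis.PurposeKeywordTable(keyword_to_category={})
        )
        assignments = lemis.classify_purpose(units, table)
        report["source_totals"] = lemis.source_totals(units)
        genus_frame, mean_wild, median_wild = lemis.genus_wild_summary(units)
        genus_frame.to_csv(out_dir / "genus_wild.csv", index=False)
        report["genus_wild"] = {
            "mean_pct_wild": mean_wild,
            "median_pct_wild": median_wild,
            "n_genera": len(genus_frame),
        }
        pd.DataFrame(
            {
                "species": [r.listed_name for r in units],
                "year": [r.year for r in units],
                "source_category": [lemis.classify_source(r) for r in units],
                "commerciality": [lemis.classify_commercial(r) for r in units],
                "use_category": [a.category for a in assignments],
                "provenance": [a.provenance for a in assignments],
            }
        ).to_csv(out_dir / "classified_shipments.csv", index=False)
        evidence["lemis"] = [
            EvidenceRecord(
                r.listed_name,
                "lemis",
                frozenset({a.category}) if a.category else frozenset(),
                r.year or None,
            )
            for r, a in zip(units, assignments)
        ]

    # stage: cites
    checklist: dict[str, str] = {}
    if config.cites_checklist is not None:
        checklist = external_sources.load_cites_checklist(
            _require(config.cites_checklist, "cites")
        )
        counts["cites_checklist"] = len(checklist)
    if config.gross_imports is not None:
        gross = external_sources.load_gross_imports(
            _require(config.gross_imports, "cites"), checklist=checklist or None
        )
        counts["gross_imports"] = len(gross)
        evidence["cites"] = [
            EvidenceRecord(g.listed_name, "cites", frozenset(), g.year) for g in gross
        ]

    # stage: iucn narratives
    if config.narratives is not None:
        narratives = external_sources.load_narratives(_require(config.narratives, "iucn"))
        counts["narratives"] = len(narratives)
        kept = 0
        evidence["iucn"] = []
        for n in narratives:
            uses = external_sources.classify_use_narrative(n)
            if uses is None:
                continue  # no-trade narratives drop out of the listings
            kept += 1
            evidence["iucn"].append(EvidenceRecord(n.listed_name, "iucn", uses, None))
        counts["narratives_in_trade"] = kept

    # stage: literature
    if config.literature is not None:
        lit, lit_unmatched = external_sources.load_literature_list(
            _require(config.literature, "literature"), index
        )
        counts["literature_species"] = len(lit)
        counts["literature_unmatched"] = len(lit_unmatched)
        evidence["literature"] = list(lit)

    # stage: merge
    profiles, unmatched = integrate.merge_sources(evidence, index)
    counts["profiles"] = len(profiles)
    counts["unmatched_names"] = len(unmatched)
    integrate.profiles_to_frame(profiles).to_csv(out_dir / "profiles.csv", index=False)
    intersections = integrate.intersect_sources(profiles.values())
    (out_dir / "intersections.json").write_text(json.dumps(intersections, indent=1))
    report["intersections"] = intersections
    crosstab = integrate.status_crosstab(profiles.values())
    crosstab.to_csv(out_dir / "status_crosstab.csv", index=False)

    if checklist:
        appendix, coverage = external_sources.join_cites_appendix(profiles.keys(), checklist)
        for sp, app in appendix.items():
            profiles[sp].cites_appendix = app
        report["cites_coverage"] = coverage

    # stage: national summary
    if config.occurrence is not None:
        occ_frame = pd.read_csv(_require(config.occurrence, "national"), dtype=str)
        occurrence: dict[str, set[str]] = {}
        for sp, country in zip(occ_frame.iloc[:, 0], occ_frame.iloc[:, 1]):
            occurrence.setdefault(str(sp).strip(), set()).add(str(country).strip())
        national = integrate.national_summary(profiles, occurrence)
        national.to_csv(out_dir / "national_summary.csv", index=False)
        report["n_countries"] = len(national)

    # stage: temporal
    if detections:
        pages_per_year: dict[int, int] = {}
        if config.pages is not None:
            for page in webscan.load_pages(Path(config.pages)):
                pages_per_year[page.year] = pages_per_year.get(page.year, 0) + 1
        series = temporal.yearly_series(detections, pages_per_year, source="online")
        series.table.to_csv(out_dir / "yearly_series.csv", index=False)
        if len(series.table) >= 3:
            fit = temporal.effort_adjusted_trend(series)
            report["trend"] = {
                "intercept": fit.intercept,
                "slope": fit.slope,
                "df": fit.degrees_of_freedom,
            }
    trade_years = {sp: sorted(p.detection_years) for sp, p in profiles.items() if p.detection_years}
    year_described = {
        c.accepted_name: c.year_described for c in concepts if c.year_described is not None
    }
    lag = temporal.description_trade_lag(
        trade_years,
        year_described,
        cutoff_year=config.cutoff_year,
        snapshot_year=config.snapshot_year,
    )
    report["lag"] = {
        "n_included": lag.n_included,
        "n_excluded_snapshot_only": lag.n_excluded_snapshot_only,
        "mean_lag": lag.mean_lag,
        "se_lag": lag.se_lag,
    }

    report["counts"] = counts
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    log_lines = [f"config_hash={report['config_hash']}"] + [
        f"{k}={v}" for k, v in sorted(counts.items())
    ]
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
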