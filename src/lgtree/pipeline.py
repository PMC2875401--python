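"""End-to-end orchestration: trees + manifest in, calls/summary/profile out,
plus the fixture-recount report reproducing the headline counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

from . import __version__
from .core_io import (
    CdsRecord,
    ClassifierConfig,
    read_group_map,
    read_newick,
)
from .lgt_classify import (
    LgtCall,
    CallSummary,
    calls_from_records,
    classify_and_infer,
    reconcile_methods,
    summarize_calls,
)

logger = logging.getLogger("lgtree")

__all__ = ["RunConfig", "ManifestEntry", "run_analysis", "recount_fixture",
           "read_manifest", "write_calls"]


@dataclass(frozen=True)
class ManifestEntry:
    gene_id: str
    query: str
    nj_tree: Path
    ml_tree: Path | None
    top_evalue: float


@dataclass
class RunConfig:
    manifest: Path
    groups: Path
    outdir: Path
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    policy: str = "conservative"
    seed: int = 0

    def validate(self) -> None:
        for p in (self.manifest, self.groups):
            if not Path(p).exists():
                raise FileNotFoundError(str(p))

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "evalue": self.classifier.evalue_threshold,
                "support": self.classifier.support_threshold,
                "focal": self.classifier.focal_group,
                "rooting": self.classifier.rooting,
                "policy": self.policy,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Manifest TSV columns: gene id, query leaf, NJ tree file, ML tree file
    (may be empty), top-hit e-value.  Paths are relative to the manifest."""
    base = Path(path).parent
    entries: list[ManifestEntry] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) < 5:
            raise ValueError(f"manifest line needs 5 columns: {raw!r}")
        entries.append(
            ManifestEntry(
                gene_id=cols[0],
                query=cols[1],
                nj_tree=base / cols[2],
                ml_tree=(base / cols[3]) if cols[3] else None,
                top_evalue=float(cols[4]),
            )
        )
    return entries


_CALL_COLUMNS = [
    "gene_id", "status", "support", "decision_groups", "donor", "direction",
    "method", "notes",
]


def write_calls(
    calls: Sequence[LgtCall], path: str | Path, header_meta: str = ""
) -> None:
    lines = [f"# lgtree {__version__}{header_meta}", "#" + "\t".join(_CALL_COLUMNS)]
    for c in calls:
        lines.append(
            "\t".join(
                [
                    c.gene_id,
                    c.status,
                    "" if c.support is None else format(c.support, ".6g"),
                    ",".join(sorted(c.decision_groups)),
                    c.donor or "",
                    c.direction,
                    c.method,
                    ";".join(c.notes),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_analysis(cfg: RunConfig) -> dict:
    """Classify every manifest gene (NJ and, when present, ML trees),
    reconcile, and write calls + summary TSVs to the output directory.

    Every gate decision is logged for auditability.  Raises with the stage
    and gene id on any per-gene failure.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups = read_group_map(cfg.groups, focal_group=cfg.classifier.focal_group)
    entries = read_manifest(cfg.manifest)

    per_method: list[LgtCall] = []
    reconciled: list[LgtCall] = []
    for entry in entries:
        try:
            nj_tree = read_newick(Path(entry.nj_tree).read_text(encoding="utf-8"))
            nj_call = classify_and_infer(
                nj_tree, entry.query, groups, entry.top_evalue,
                cfg.classifier, method="nj",
            )
            logger.info(
                "gene %s [nj]: status=%s support=%s groups=%s",
                entry.gene_id, nj_call.status, nj_call.support,
                sorted(nj_call.decision_groups),
            )
            nj_call.gene_id = entry.gene_id
            per_method.append(nj_call)
            if entry.ml_tree is not None:
                ml_tree = read_newick(
                    Path(entry.ml_tree).read_text(encoding="utf-8")
                )
                ml_call = classify_and_infer(
                    ml_tree, entry.query, groups, entry.top_evalue,
                    cfg.classifier, method="ml",
                )
                ml_call.gene_id = entry.gene_id
                logger.info(
                    "gene %s [ml]: status=%s support=%s groups=%s",
                    entry.gene_id, ml_call.status, ml_call.support,
                    sorted(ml_call.decision_groups),
                )
                per_method.append(ml_call)
                reconciled.append(reconcile_methods(nj_call, ml_call, cfg.policy))
            else:
                reconciled.append(nj_call)
        except Exception as exc:
            raise RuntimeError(
                f"classification failed at gene {entry.gene_id!r}: {exc}"
            ) from exc

    meta = f" seed={cfg.seed} config={cfg.config_hash()}"
    write_calls(per_method, outdir / "calls_per_method.tsv", meta)
    write_calls(reconciled, outdir / "calls.tsv", meta)
    summary = summarize_calls(reconciled)
    summary_lines = [f"# lgtree {__version__}{meta}"]
    for key in ("total", "lgt", "no_lgt", "unresolved", "novel",
                "direction_resolved", "discordant"):
        summary_lines.append(f"{key}\t{getattr(summary, key)}")
    for donor, n in summary.per_donor:
        summary_lines.append(f"donor:{donor}\t{n}")
    (outdir / "summary.tsv").write_text(
        "\n".join(summary_lines) + "\n", encoding="utf-8"
    )
    return {"summary": summary, "calls": reconciled, "outdir": str(outdir)}


def _round_half_up(x: float) -> int:
    return int(Decimal(str(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def recount_fixture(records: Sequence[CdsRecord]) -> dict:
    """Recompute the headline counts from a CDS fixture table.

    Pure function of the fixture.  "LGT count" uses the conservative
    NJ/ML-reconciled calls; percentages are rounded half-up with the raw
    fraction also reported.
    """
    coding = [r for r in records if r.is_coding]
    calls = calls_from_records(records)
    by_gene = {c.gene_id: c for c in calls}
    summary: CallSummary = summarize_calls(calls)

    def call_for(rec: CdsRecord) -> LgtCall:
        return by_gene[f"{rec.fosmid}:{rec.cds_index}"]

    nonfocal = [r for r in coding if not r.top_hit_in_focal_group]
    transposases = [r for r in coding if "transposase" in r.function.lower()]
    integrases = [r for r in coding if "integrase" in r.function.lower()]
    native_transposases = [
        r for r in transposases if call_for(r).status == "no_lgt"
    ]
    discordant = [r for r in coding if r.nj_lgt != r.ml_lgt]
    frac = len(nonfocal) / len(coding) if coding else 0.0

    return {
        "coding_total": len(coding),
        "lgt_count": summary.lgt,
        "direction_resolved_count": summary.direction_resolved,
        "direction_to_focal_from_XIVa": summary.donor_count("cluster_XIVa"),
        "nonfocal_tophit_count": len(nonfocal),
        "nonfocal_tophit_fraction": frac,
        "nonfocal_tophit_percent": _round_half_up(100.0 * frac),
        "transposase_count": len(transposases),
        "integrase_count": len(integrases),
        "native_transposase_count": len(native_transposases),
        "nj_ml_discordant_count": len(discordant),
        "novel_count": summary.novel,
        "unresolved_count": summary.unresolved,
        "no_lgt_count": summary.no_lgt,
    }
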