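"""Readers and writers binding the pipeline stages together.

Formats: paired timecourses as TSV (long format: time_min, condition,
peptides_per_ribosome, plateau) with the full simulation config embedded as a
``# config:`` JSON header; fit results as JSON; miner candidates as TSV and
GFF3; sequences as FASTA; anchors as 6-column BED.  Every writer's output is
readable by the matching reader with full value fidelity.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fitting import FitResult
from .kinetics import RecyclingParams
from .mining import AnchorRegion, PrecursorCandidate
from .simulate import AssayConfig, AssayTimecourse, SyntheticNeighborhood

__all__ = [
    "write_timecourse_tsv",
    "read_timecourse_tsv",
    "write_fit_json",
    "read_fit_json",
    "write_candidates_tsv",
    "read_candidates_tsv",
    "write_candidates_gff3",
    "write_fasta",
    "read_fasta",
    "read_anchor_bed",
    "write_anchor_bed",
    "write_neighborhood",
]


class DataFormatError(ValueError):
    """Malformed input file; message names the offending record/line."""


def _config_to_dict(cfg: AssayConfig) -> dict:
    return {
        "P": cfg.params.P,
        "k": cfg.params.k,
        "timepoints": list(cfg.timepoints),
        "n_ribosomes": cfg.n_ribosomes,
        "competitor_present": cfg.competitor_present,
        "competitor_excess": cfg.competitor_excess,
        "fmet_excess": cfg.fmet_excess,
        "noise_cv": cfg.noise_cv,
        "seed": cfg.seed,
    }


def _config_from_dict(d: dict) -> AssayConfig:
    d = dict(d)
    params = RecyclingParams(P=d.pop("P"), k=d.pop("k"))
    d["timepoints"] = tuple(d["timepoints"])
    return AssayConfig(params=params, **d)


def write_timecourse_tsv(tc: AssayTimecourse, path: str | Path) -> None:
    path = Path(path)
    lines = ["# ribocycle competition-assay timecourse"]
    lines.append("# config: " + json.dumps(_config_to_dict(tc.config), sort_keys=True))
    lines.append("time_min\tcondition\tpeptides_per_ribosome\tplateau")
    for cond, y, plat in (
        ("with_competitor", tc.with_competitor, tc.plateau_with),
        ("without_competitor", tc.without_competitor, tc.plateau_without),
    ):
        for t, v, p in zip(tc.timepoints, y, plat):
            lines.append(f"{float(t)!r}\t{cond}\t{float(v)!r}\t{int(p)}")
    path.write_text("\n".join(lines) + "\n")


def read_timecourse_tsv(path: str | Path) -> AssayTimecourse:
    path = Path(path)
    cfg = None
    body: list[str] = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if line.startswith("# config:"):
            try:
                cfg = _config_from_dict(json.loads(line.split(":", 1)[1]))
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise DataFormatError(f"{path}:{ln}: bad config header: {exc}") from exc
        elif not line.startswith("#"):
            body.append(line)
    try:
        df = pd.read_csv(
            _io.StringIO("\n".join(body)), sep="\t", float_precision="round_trip"
        )
    except Exception as exc:  # pandas raises several parser error types
        raise DataFormatError(f"{path}: cannot parse TSV body: {exc}") from exc
    required = {"time_min", "condition", "peptides_per_ribosome"}
    if not required <= set(df.columns):
        raise DataFormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if "plateau" not in df.columns:
        df["plateau"] = 0
    series = {}
    for cond in ("with_competitor", "without_competitor"):
        sub = df[df["condition"] == cond].sort_values("time_min")
        if sub.empty:
            raise DataFormatError(f"{path}: no rows for condition {cond!r}")
        series[cond] = sub
    t = series["with_competitor"]["time_min"].to_numpy(dtype=float)
    t2 = series["without_competitor"]["time_min"].to_numpy(dtype=float)
    if t.shape != t2.shape or not np.allclose(t, t2):
        raise DataFormatError(f"{path}: conditions sampled on different time grids")
    if cfg is None:
        cfg = AssayConfig(
            params=RecyclingParams(P=0.5, k=1.0), timepoints=tuple(t), seed=0
        )
    return AssayTimecourse(
        timepoints=t,
        with_competitor=series["with_competitor"]["peptides_per_ribosome"].to_numpy(float),
        without_competitor=series["without_competitor"]["peptides_per_ribosome"].to_numpy(float),
        plateau_with=series["with_competitor"]["plateau"].to_numpy(bool),
        plateau_without=series["without_competitor"]["plateau"].to_numpy(bool),
        config=cfg,
    )


def write_fit_json(fit: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2, sort_keys=True) + "\n")


def read_fit_json(path: str | Path) -> FitResult:
    try:
        return FitResult(**json.loads(Path(path).read_text()))
    except (json.JSONDecodeError, TypeError) as exc:
        raise DataFormatError(f"{path}: not a fit-result JSON: {exc}") from exc


_CAND_COLS = [
    "sequence_id", "start", "end", "strand", "peptide", "length_aa",
    "length_class", "sd_score", "sd_spacer_nt", "sd_edge", "same_strand",
    "upstream", "distance_nt", "rank_score",
]


def write_candidates_tsv(cands: list[PrecursorCandidate], path: str | Path) -> None:
    rows = [{c: getattr(cand, c) for c in _CAND_COLS} for cand in cands]
    df = pd.DataFrame(rows, columns=_CAND_COLS)
    for col in ("sd_edge", "same_strand", "upstream"):
        df[col] = df[col].astype(int) if len(df) else df[col]
    df.to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str | Path) -> list[PrecursorCandidate]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise DataFormatError(f"{path}: cannot parse candidate TSV: {exc}") from exc
    out = []
    for _, row in df.iterrows():
        d = {c: row[c] for c in _CAND_COLS}
        for col in ("start", "end", "length_aa", "sd_score", "sd_spacer_nt",
                    "distance_nt", "rank_score"):
            d[col] = int(d[col])
        for col in ("sd_edge", "same_strand", "upstream"):
            d[col] = bool(d[col])
        out.append(PrecursorCandidate(**d))
    return out


def write_candidates_gff3(cands: list[PrecursorCandidate], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for i, c in enumerate(cands, 1):
        attrs = (
            f"ID=precursor{i};peptide={c.peptide};length_class={c.length_class};"
            f"sd_score={c.sd_score};sd_spacer={c.sd_spacer_nt};"
            f"distance_nt={c.distance_nt};rank_score={c.rank_score}"
        )
        lines.append(
            "\t".join(
                [
                    c.sequence_id, "ribocycle", "ORF",
                    str(c.start + 1), str(c.end),  # GFF3 is 1-based inclusive
                    str(c.rank_score), c.strand, "0", attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    try:
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    except Exception as exc:
        raise DataFormatError(f"{path}: cannot parse FASTA: {exc}") from exc
    if not records:
        raise DataFormatError(f"{path}: no FASTA records found")
    return records


def read_anchor_bed(path: str | Path, window_nt: int = 300) -> list[AnchorRegion]:
    """Read anchors from 6-column BED (chrom, start, end, name, score, strand)."""
    anchors = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise DataFormatError(f"{path}:{ln}: expected 6 BED columns, got {len(parts)}")
        try:
            anchors.append(
                AnchorRegion(
                    sequence_id=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    strand=parts[5],
                    window_nt=window_nt,
                )
            )
        except ValueError as exc:
            raise DataFormatError(f"{path}:{ln}: {exc}") from exc
    if not anchors:
        raise DataFormatError(f"{path}: no anchor intervals found")
    return anchors


def write_anchor_bed(anchors: list[AnchorRegion], path: str | Path) -> None:
    lines = [
        f"{a.sequence_id}\t{a.start}\t{a.end}\tanchor{i}\t0\t{a.strand}"
        for i, a in enumerate(anchors, 1)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_neighborhood(nbh: SyntheticNeighborhood, prefix: str | Path) -> dict[str, Path]:
    """Write a synthetic neighborhood as FASTA + BED + ground-truth JSON.

    Returns the paths written, keyed by kind.  The BED holds the anchor and,
    if planted, the precursor ORF interval."""
    prefix = Path(prefix)
    name = prefix.name or "neighborhood"
    fasta = prefix.with_suffix(".fasta")
    bed = prefix.with_suffix(".bed")
    truth = prefix.with_suffix(".truth.json")
    write_fasta({name: nbh.sequence}, fasta)
    lines = [f"{name}\t{nbh.anchor_start}\t{nbh.anchor_end}\tanchor\t0\t{nbh.anchor_strand}"]
    if nbh.planted_orf is not None:
        s, e, strand = nbh.planted_orf
        lines.append(f"{name}\t{s}\t{e}\tplanted_orf\t0\t{strand}")
    bed.write_text("\n".join(lines) + "\n")
    truth.write_text(nbh.ground_truth_json() + "\n")
    return {"fasta": fasta, "bed": bed, "truth": truth}
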