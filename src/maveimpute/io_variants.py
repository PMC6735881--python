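"""Readers, writers and identity types for variant score data.

Canonical on-disk formats
-------------------------
Score table
    Delimited text (comma or tab, auto-detected) with a header.
    Required columns: ``variant`` (compact ``R123H`` / ``W10*`` / ``L7=``
    or HGVS-p ``p.Arg123His``) and ``score``. Optional: ``sd`` (per-variant
    standard deviation across replicates), ``n_reps`` (replicate count,
    default 1) and ``quality`` (experiment-supplied quality score, default
    ``n_reps``). Duplicate variants are merged by replicate-count-weighted
    mean with pooled dispersion.
Wild-type sequence
    FASTA; the first record is used.
Structure annotations
    TSV with columns ``position``, ``ss_class`` in {H, E, C} and
    ``rsa`` in [0, 1].
External predictor scores
    TSV with a ``variant`` column plus any subset of ``polyphen2``,
    ``provean``, ``sift``; blanks allowed.
Variant-effect map
    TSV long format (one row per position x substitution cell) with
    columns ``position, wt, alt, score, stderr, provenance``; headed by
    ``#`` comment lines carrying the normalization anchors and run
    metadata so that write -> read round-trips losslessly.

Positions are 1-based protein residue indices throughout (HGVS
convention).
"""

from __future__ import annotations

import dataclasses
import io
import json
import logging
import math
import re
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .aminoacids import AA_ALPHABET, STOP, SYNONYMOUS, THREE_TO_ONE, ONE_TO_THREE
from .exceptions import FormatError, ParseError

log = logging.getLogger(__name__)

_VALID_ALT = set(AA_ALPHABET) | {STOP, SYNONYMOUS}

_COMPACT_RE = re.compile(r"^([A-Z])(\d+)([A-Z*=])$")
_HGVS_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|\*|=)$")


@dataclasses.dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a single amino-acid substitution.

    ``alt`` is a one-letter amino-acid code, ``'*'`` for stop, or ``'='``
    for synonymous. A synonymous substitution written as ``alt == wt`` is
    canonicalized to ``'='`` at parse time.
    """

    position: int
    wt: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ParseError(f"position must be >= 1, got {self.position}")
        if self.wt not in AA_ALPHABET:
            raise ParseError(f"unknown wild-type residue {self.wt!r}")
        if self.alt not in _VALID_ALT:
            raise ParseError(f"unknown substitution {self.alt!r}")

    @property
    def is_stop(self) -> bool:
        return self.alt == STOP

    @property
    def is_synonymous(self) -> bool:
        return self.alt == SYNONYMOUS

    @property
    def is_missense(self) -> bool:
        return self.alt in AA_ALPHABET and self.alt != self.wt

    @property
    def token(self) -> str:
        """Compact one-letter token, e.g. ``R123H``, ``W10*``, ``L7=``."""
        return f"{self.wt}{self.position}{self.alt}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


@dataclasses.dataclass(frozen=True)
class MeasuredRecord:
    """One experimental measurement of a variant's function score."""

    key: VariantKey
    score: float
    sd: float = math.nan
    n_reps: int = 1
    quality: float = math.nan

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise FormatError(f"{self.key}: n_reps must be >= 1")
        if math.isfinite(self.sd) and self.sd < 0:
            raise FormatError(f"{self.key}: sd must be >= 0")


@dataclasses.dataclass
class ProteinContext:
    """Wild-type sequence plus optional per-position structural annotation."""

    sequence: str
    uniprot_id: Optional[str] = None
    structure: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError("wild-type sequence is empty")
        bad = set(self.sequence) - set(AA_ALPHABET)
        if bad:
            raise FormatError(
                f"wild-type sequence contains non-amino-acid letters: {sorted(bad)}"
            )
        if self.structure is not None:
            pos = self.structure["position"]
            if (pos < 1).any() or (pos > len(self.sequence)).any():
                raise FormatError("structure annotations outside sequence range")

    def __len__(self) -> int:
        return len(self.sequence)

    def wt_at(self, position: int) -> str:
        return self.sequence[position - 1]


def parse_variant(token: str) -> VariantKey:
    """Parse a compact or HGVS-p variant token into a :class:`VariantKey`.

    Synonymous forms (``alt == wt``, ``=``) are canonicalized to ``'='``;
    ``Ter`` and ``*`` both denote stop.
    """
    tok = str(token).strip()
    m = _COMPACT_RE.match(tok)
    if m:
        wt, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    else:
        m = _HGVS_RE.match(tok)
        if not m:
            raise ParseError(f"cannot parse variant token {token!r}")
        wt3, pos, alt3 = m.group(1), int(m.group(2)), m.group(3)
        if wt3 not in THREE_TO_ONE or wt3 == "Ter":
            raise ParseError(f"unknown residue code {wt3!r} in {token!r}")
        wt = THREE_TO_ONE[wt3]
        if alt3 in ("=",):
            alt = SYNONYMOUS
        elif alt3 == "*":
            alt = STOP
        else:
            if alt3 not in THREE_TO_ONE:
                raise ParseError(f"unknown residue code {alt3!r} in {token!r}")
            alt = THREE_TO_ONE[alt3]
    if alt == wt:
        alt = SYNONYMOUS
    try:
        return VariantKey(pos, wt, alt)
    except ParseError as exc:
        raise ParseError(f"{token!r}: {exc}") from None


def format_variant(key: VariantKey) -> str:
    """Inverse of :func:`parse_variant` (compact form)."""
    return key.token


_SCORE_COLUMNS = ["variant", "position", "wt", "alt", "score", "sd", "n_reps", "quality"]


def _merge_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Merge rows sharing a VariantKey by replicate-count-weighted mean.

    The pooled sd combines within-row and between-row dispersion; quality
    is averaged with replicate weights and replicate counts are summed.
    """

    def pool(group: pd.DataFrame) -> pd.Series:
        if len(group) == 1:
            return group.iloc[0][["score", "sd", "n_reps", "quality"]]
        n = group["n_reps"].to_numpy(dtype=float)
        x = group["score"].to_numpy(dtype=float)
        s = group["sd"].to_numpy(dtype=float)
        ntot = n.sum()
        mean = float(np.average(x, weights=n))
        if np.isfinite(s).all() and ntot > 1:
            within = ((n - 1) * s**2).sum()
            between = (n * (x - mean) ** 2).sum()
            sd = float(math.sqrt((within + between) / (ntot - 1)))
        else:
            sd = math.nan
        quality = float(np.average(group["quality"].to_numpy(dtype=float), weights=n))
        return pd.Series(
            {"score": mean, "sd": sd, "n_reps": int(ntot), "quality": quality}
        )

    merged = (
        df.groupby(["position", "wt", "alt"], sort=True)
        .apply(pool, include_groups=False)
        .reset_index()
    )
    merged["n_reps"] = merged["n_reps"].astype(int)
    merged["variant"] = [
        VariantKey(int(r.position), r.wt, r.alt).token for r in merged.itertuples()
    ]
    return merged[_SCORE_COLUMNS]


def read_score_table(path, *, max_bad_fraction: float = 0.05) -> pd.DataFrame:
    """Read and validate a variant score table.

    Returns a DataFrame with columns ``variant, position, wt, alt, score,
    sd, n_reps, quality``, one row per VariantKey (duplicates merged),
    sorted by position then substitution. Per-row parse failures are
    collected; the read aborts if they exceed ``max_bad_fraction`` of
    rows.
    """
    raw = pd.read_csv(path, sep=None, engine="python", dtype={"variant": str})
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    for col in ("variant", "score"):
        if col not in raw.columns:
            raise FormatError(f"{path}: required column {col!r} missing")

    rows = []
    errors: list[str] = []
    for idx, row in raw.iterrows():
        try:
            key = parse_variant(row["variant"])
            score = float(row["score"])
            if not math.isfinite(score):
                raise FormatError(f"{row['variant']}: non-finite score")
            sd = float(row["sd"]) if "sd" in raw.columns else math.nan
            if math.isfinite(sd) and sd < 0:
                raise FormatError(f"{row['variant']}: negative sd")
            n_reps = row.get("n_reps", math.nan)
            n_reps = int(n_reps) if pd.notna(n_reps) else 1
            if n_reps < 1:
                raise FormatError(f"{row['variant']}: n_reps must be >= 1")
            quality = row.get("quality", math.nan)
            quality = float(quality) if pd.notna(quality) else float(n_reps)
            rows.append(
                (key.token, key.position, key.wt, key.alt, score, sd, n_reps, quality)
            )
        except (ParseError, FormatError, ValueError) as exc:
            errors.append(f"row {idx + 2}: {exc}")

    n_read = len(raw)
    if n_read == 0:
        raise FormatError(f"{path}: empty score table")
    if len(errors) > max_bad_fraction * n_read:
        detail = "; ".join(errors[:10])
        raise FormatError(
            f"{path}: {len(errors)}/{n_read} rows unreadable "
            f"(> {max_bad_fraction:.0%} allowed): {detail}"
        )

    df = pd.DataFrame(rows, columns=_SCORE_COLUMNS)
    n_before = len(df)
    df = _merge_duplicates(df)
    df = df.sort_values(["position", "alt"], kind="mergesort").reset_index(drop=True)
    log.info(
        "read %d rows from %s: %d rejected, %d merged, %d records",
        n_read, path, len(errors), n_before - len(df), len(df),
    )
    df.attrs.update(
        n_rows_read=n_read, n_rejected=len(errors), n_merged=n_before - len(df),
        row_errors=errors,
    )
    return df


def write_score_table(df: pd.DataFrame, path) -> None:
    """Write a score table in the canonical TSV dialect."""
    out = df[["variant", "score", "sd", "n_reps", "quality"]]
    out.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> ProteinContext:
    """Read the wild-type protein sequence (first FASTA record)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    rec = records[0]
    return ProteinContext(sequence=str(rec.seq).upper(), uniprot_id=rec.id or None)


def read_structure(path) -> pd.DataFrame:
    """Read per-position structure annotations (position, ss_class, rsa)."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("position", "ss_class", "rsa"):
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} missing")
    df["position"] = df["position"].astype(int)
    bad_ss = set(df["ss_class"]) - {"H", "E", "C"}
    if bad_ss:
        raise FormatError(f"{path}: ss_class must be H/E/C, got {sorted(bad_ss)}")
    rsa = df["rsa"].astype(float)
    if ((rsa < 0) | (rsa > 1)).any():
        raise FormatError(f"{path}: rsa must lie in [0, 1]")
    if df["position"].duplicated().any():
        raise FormatError(f"{path}: duplicate positions in structure file")
    return df[["position", "ss_class", "rsa"]].reset_index(drop=True)


PREDICTOR_COLUMNS = ("polyphen2", "provean", "sift")


def read_predictors(path) -> pd.DataFrame:
    """Read external per-variant predictor scores (any subset of columns)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={"variant": str})
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "variant" not in df.columns:
        raise FormatError(f"{path}: required column 'variant' missing")
    present = [c for c in PREDICTOR_COLUMNS if c in df.columns]
    if not present:
        raise FormatError(
            f"{path}: no predictor columns found (expected any of {PREDICTOR_COLUMNS})"
        )
    keys = [parse_variant(t) for t in df["variant"]]
    out = pd.DataFrame(
        {
            "variant": [k.token for k in keys],
            "position": [k.position for k in keys],
            "wt": [k.wt for k in keys],
            "alt": [k.alt for k in keys],
        }
    )
    for col in present:
        out[col] = pd.to_numeric(df[col], errors="coerce").to_numpy()
    if out["variant"].duplicated().any():
        dups = out.loc[out["variant"].duplicated(), "variant"].tolist()[:5]
        raise FormatError(f"{path}: duplicate predictor rows for {dups}")
    return out


def validate_against_sequence(df: pd.DataFrame, context: ProteinContext) -> None:
    """Check that every record's position and wt residue match the sequence."""
    problems = []
    for row in df.itertuples():
        if row.position > len(context):
            problems.append(f"{row.variant}: position beyond sequence length {len(context)}")
        elif context.wt_at(row.position) != row.wt:
            problems.append(
                f"{row.variant}: wild-type mismatch "
                f"(sequence has {context.wt_at(row.position)})"
            )
    if problems:
        raise FormatError(
            f"{len(problems)} records disagree with the wild-type sequence: "
            + "; ".join(problems[:10])
        )


_VEMAP_MAGIC = "#maveimpute-vemap v1"


def write_vemap(vemap, path) -> None:
    """Write a complete variant-effect map as annotated long-format TSV."""
    frame = vemap.to_frame()
    anchors = vemap.anchors
    header = [_VEMAP_MAGIC]
    if anchors is not None:
        header.append(
            "#anchors: "
            + json.dumps(
                {"stop_median": anchors.stop_median, "syn_median": anchors.syn_median}
            )
        )
    header.append("#metadata: " + json.dumps(vemap.metadata, sort_keys=True, default=str))
    buf = io.StringIO()
    # shortest round-trip float text, so read_vemap restores full precision
    frame.to_csv(buf, sep="\t", index=False, float_format=lambda x: repr(float(x)))
    Path(path).write_text("\n".join(header) + "\n" + buf.getvalue())


def read_vemap(path):
    """Read a map written by :func:`write_vemap` (lossless round trip)."""
    from .normalize import ScaleAnchors
    from .refine import VEMap

    text = Path(path).read_text().splitlines()
    if not text or text[0] != _VEMAP_MAGIC:
        raise FormatError(f"{path}: not a maveimpute variant-effect map file")
    anchors = None
    metadata: dict = {}
    body_start = 1
    for i, line in enumerate(text[1:], start=1):
        if line.startswith("#anchors: "):
            d = json.loads(line[len("#anchors: "):])
            anchors = ScaleAnchors(d["stop_median"], d["syn_median"])
        elif line.startswith("#metadata: "):
            metadata = json.loads(line[len("#metadata: "):])
        elif not line.startswith("#"):
            body_start = i
            break
    frame = pd.read_csv(
        io.StringIO("\n".join(text[body_start:])),
        sep="\t",
        dtype={"wt": str, "alt": str, "provenance": str},
        float_precision="round_trip",
    )
    frame["position"] = frame["position"].astype(int)
    return VEMap(frame=frame, anchors=anchors, metadata=metadata)


def records_to_frame(records: Iterable[MeasuredRecord]) -> pd.DataFrame:
    """Convert :class:`MeasuredRecord` objects to the canonical DataFrame."""
    rows = [
        (r.key.token, r.key.position, r.key.wt, r.key.alt, r.score, r.sd, r.n_reps,
         r.quality if math.isfinite(r.quality) else float(r.n_reps))
        for r in records
    ]
    return pd.DataFrame(rows, columns=_SCORE_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[MeasuredRecord]:
    """Inverse of :func:`records_to_frame`."""
    return [
        MeasuredRecord(
            key=VariantKey(int(r.position), r.wt, r.alt),
            score=float(r.score), sd=float(r.sd), n_reps=int(r.n_reps),
            quality=float(r.quality),
        )
        for r in df.itertuples()
    ]
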