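"""File formats: expression matrices, result directories, run manifests.

All outputs are plain text (TSV/JSON) so results are portable and
diff-able.  A result directory contains:

* ``signatures.tsv`` — one row per signature (label, term, component,
  p-value, enrichment score, cutoff, gene list);
* ``signature_matrix.tsv`` — the signatures x samples expression matrix in
  persisted (clustered) order;
* ``config.json`` — the fully resolved configuration plus provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import GopcaConfig, GopcaResult, Signature
from .enrichment import EnrichmentResult

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "write_signature_matrix_tsv",
    "read_signature_matrix_tsv",
    "write_result",
    "read_result",
    "RunManifest",
]


def read_expression_tsv(
    path: str | Path,
    duplicate_policy: str = "error",
    na_policy: str = "error",
) -> pd.DataFrame:
    """Read a tab-delimited genes x samples expression matrix.

    The first column holds gene names and the header row sample names; all
    values must parse as finite reals.  ``duplicate_policy`` controls rows
    sharing a gene name: ``error`` (default) or ``keep-max-mean`` (keep the
    row with the highest mean expression — the conventional rule when
    multiple probesets map to one gene).  ``na_policy``: ``error`` (default)
    or ``impute-median`` (replace missing cells by the gene's median).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if not samples:
        raise ValueError(f"{path}: no sample columns found")
    if len(set(samples)) < len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample names: {dups[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric expression values: {exc}") from exc
    df = values
    if df.isna().any().any():
        if na_policy == "impute-median":
            n_missing = int(df.isna().sum().sum())
            df = df.apply(lambda row: row.fillna(row.median()), axis=1)
            logger.warning("%s: imputed %d missing values with gene medians",
                           path, n_missing)
        else:
            gene = df.index[df.isna().any(axis=1)][0]
            raise ValueError(f"{path}: missing value in gene {gene!r}")
    if df.index.duplicated().any():
        if duplicate_policy == "keep-max-mean":
            means = df.mean(axis=1)
            order = np.argsort(-means.to_numpy(), kind="stable")
            ranked = df.iloc[order]
            kept = ranked[~ranked.index.duplicated(keep="first")]
            df = kept.loc[[g for g in df.index.unique()]]
            logger.info("%s: collapsed duplicate gene rows (keep-max-mean)", path)
        else:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"{path}: duplicate gene names: {dups[:5]}")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: non-finite expression values")
    logger.info("read_expression_tsv: %d genes x %d samples from %s",
                df.shape[0], df.shape[1], path)
    return df


def write_expression_tsv(E: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix in the format read by
    :func:`read_expression_tsv`."""
    E.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def write_signature_matrix_tsv(result: GopcaResult, path: str | Path) -> None:
    """Write the signatures x samples matrix with descriptive row labels.

    Row labels follow the ``"<NS> <name> (pc, n_genes, K)"`` convention,
    where a negative component index marks enrichment among the lowest
    loadings.  Values carry 6 significant digits.
    """
    if result.n_signatures < 1:
        raise ValueError("result has no signatures")
    result.matrix.to_csv(path, sep="\t", index_label="signature",
                         float_format="%.6g")


def read_signature_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


_SIG_COLUMNS = [
    "label", "term_id", "name", "namespace", "pc", "p_mhg", "s_mhg",
    "escore", "n_star", "k_star", "K", "N", "X", "L", "genes",
]


def _signatures_frame(result: GopcaResult) -> pd.DataFrame:
    rows = []
    for s in result.signatures:
        e = s.enrichment
        rows.append({
            "label": s.label, "term_id": s.term_id, "name": s.name,
            "namespace": s.namespace, "pc": s.pc_index,
            "p_mhg": e.p_mhg, "s_mhg": e.s_mhg, "escore": e.escore,
            "n_star": e.n_star, "k_star": e.k_star, "K": e.K, "N": e.N,
            "X": e.X, "L": e.L, "genes": ",".join(s.genes),
        })
    return pd.DataFrame(rows, columns=_SIG_COLUMNS)


def write_result(result: GopcaResult, out_dir: str | Path) -> Path:
    """Serialize a result to a directory of text files; returns the path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _signatures_frame(result).to_csv(out_dir / "signatures.tsv", sep="\t",
                                     index=False)
    if result.n_signatures:
        write_signature_matrix_tsv(result, out_dir / "signature_matrix.tsv")
    payload = {
        "config": dataclasses.asdict(result.config),
        "D": result.D,
        "n_signatures": result.n_signatures,
        "provenance": result.provenance,
        "version": __version__,
    }
    (out_dir / "config.json").write_text(json.dumps(payload, indent=2) + "\n")
    return out_dir


def read_result(path: str | Path) -> GopcaResult:
    """Reconstruct a result from a directory written by :func:`write_result`.

    Expression values round-trip to the 6 significant digits of the TSV
    format.
    """
    path = Path(path)
    payload = json.loads((path / "config.json").read_text())
    config = GopcaConfig(**payload["config"])
    sig_frame = pd.read_csv(path / "signatures.tsv", sep="\t")
    matrix_path = path / "signature_matrix.tsv"
    matrix = (read_signature_matrix_tsv(matrix_path) if matrix_path.exists()
              else pd.DataFrame())
    signatures = []
    for _, row in sig_frame.iterrows():
        enr = EnrichmentResult(
            term_id=row["term_id"], term_name=row["name"],
            namespace=row["namespace"], pc_index=int(row["pc"]),
            s_mhg=float(row["s_mhg"]), p_mhg=float(row["p_mhg"]),
            n_star=int(row["n_star"]), k_star=int(row["k_star"]),
            K=int(row["K"]), N=int(row["N"]), X=int(row["X"]), L=int(row["L"]),
            escore=float(row["escore"]),
        )
        expression = (matrix.loc[row["label"]] if row["label"] in matrix.index
                      else pd.Series(dtype=float))
        signatures.append(Signature(
            term_id=row["term_id"], name=row["name"],
            namespace=row["namespace"], pc_index=int(row["pc"]),
            genes=tuple(str(row["genes"]).split(",")) if row["genes"] else (),
            expression=expression, enrichment=enr, K_total=int(row["K"]),
        ))
    return GopcaResult(
        config=config, D=int(payload["D"]), signatures=signatures,
        matrix=matrix, provenance=payload.get("provenance", {}),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every command-line output."""

    inputs: dict[str, dict] = dataclasses.field(default_factory=dict)
    outputs: dict[str, dict] = dataclasses.field(default_factory=dict)
    config: dict = dataclasses.field(default_factory=dict)
    counts: dict = dataclasses.field(default_factory=dict)
    timings: dict = dataclasses.field(default_factory=dict)
    version: str = __version__
    created: str = ""

    def add_input(self, name: str, path: str | Path) -> None:
        p = Path(path)
        self.inputs[name] = {"path": str(p), "sha256": _sha256(p)}

    def add_output(self, name: str, path: str | Path) -> None:
        p = Path(path)
        self.outputs[name] = {"path": str(p), "sha256": _sha256(p)}

    def write(self, path: str | Path) -> None:
        self.created = datetime.now(timezone.utc).isoformat()
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n"
        )
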