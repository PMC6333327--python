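"""Deterministic TSV/PDB report writers.

Every text output starts with comment lines naming the package version and
a hash of the resolved configuration, so a rerun on identical inputs is
byte-identical and auditable.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from . import __version__

FLOAT_FMT = "%.6g"


def config_hash(config: dict) -> str:
    """Stable short hash of a flat configuration mapping."""
    payload = "\n".join(f"{k}={config[k]}" for k in sorted(config))
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def header_lines(config: dict) -> list[str]:
    lines = [
        f"# nonaffine {__version__}  config_hash={config_hash(config)}",
    ]
    lines += [f"# {k} = {config[k]}" for k in sorted(config)]
    return lines


def write_table(path, table: pd.DataFrame, config: dict) -> None:
    """Write a DataFrame as TSV with the config header."""
    with open(path, "w") as fh:
        for line in header_lines(config):
            fh.write(line + "\n")
        table.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def write_matrix(path, matrix: np.ndarray, labels, config: dict) -> None:
    """Write a square matrix as TSV with a label header row and column."""
    labels = list(labels)
    with open(path, "w") as fh:
        for line in header_lines(config):
            fh.write(line + "\n")
        fh.write("residue_id\t" + "\t".join(str(l) for l in labels) + "\n")
        for label, row in zip(labels, matrix):
            fh.write(str(label) + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")


def write_spectrum(path, site: int, spectrum, config: dict) -> None:
    """Spectrum table: site id, rank, eigenvalue, normalized eigenvalue."""
    table = pd.DataFrame(
        {
            "site": site,
            "rank": np.arange(1, len(spectrum.eigenvalues) + 1),
            "eigenvalue": spectrum.eigenvalues,
            "normalized": spectrum.normalized_eigenvalues,
        }
    )
    write_table(path, table, config)


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, skipping header comments."""
    return pd.read_csv(path, sep="\t", comment="#")
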