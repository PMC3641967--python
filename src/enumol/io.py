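"""Molecule readers/writers and provenance-stamped output files."""

from __future__ import annotations

import logging
from pathlib import Path

from rdkit import Chem

logger = logging.getLogger("enumol")

__all__ = ["read_molecules", "write_smiles", "write_sdf", "ReadReport"]


class ReadError(RuntimeError):
    pass


class ReadReport:
    """Counts of parsed and failed records from the last read."""

    def __init__(self):
        self.n_ok = 0
        self.n_failed = 0
        self.failures = []  # (record index, reason)


def _iter_smiles(path, report):
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            token = line.split()[0]
            mol = Chem.MolFromSmiles(token)
            if mol is None:
                report.n_failed += 1
                report.failures.append((lineno, token))
                logger.warning("line %d: unparseable SMILES %r",
                               lineno, token)
                continue
            report.n_ok += 1
            yield mol


def _iter_sdf(path, report):
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            report.n_failed += 1
            report.failures.append((i, "sdf record"))
            logger.warning("SDF record %d unparseable", i)
            continue
        report.n_ok += 1
        yield mol


def read_molecules(path, fmt: str | None = None):
    """Read molecules from a SMILES (.smi/.txt) or SDF (.sdf) file.

    Returns ``(molecules, report)``; unparseable records are counted and
    logged, not fatal, but more than 50% failures raises.
    """
    path = Path(path)
    if not path.exists():
        raise ReadError(f"no such file: {path}")
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() == ".sdf" else "smiles"
    report = ReadReport()
    reader = _iter_sdf if fmt == "sdf" else _iter_smiles
    mols = list(reader(path, report))
    total = report.n_ok + report.n_failed
    if total and report.n_failed / total > 0.5:
        raise ReadError(
            f"{report.n_failed}/{total} records failed to parse in {path}; "
            f"first failures: {report.failures[:5]}")
    return mols, report


def write_smiles(path, records, header_lines=()):
    """Write records as tab-separated SMILES lines.

    ``records`` yields either SMILES strings or objects with ``smiles``
    plus optional provenance attributes (``index``).  Header lines are
    written as # comments.
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for rec in records:
            if isinstance(rec, str):
                fh.write(rec + "\n")
            else:
                fh.write(f"{rec.smiles}\t{rec.index}\n")


def write_sdf(path, mols, properties=None):
    """Write an SDF (v2000); ``properties`` maps names to per-molecule
    value lists stored as SD tags."""
    writer = Chem.SDWriter(str(path))
    try:
        for i, mol in enumerate(mols):
            if properties:
                for key, values in properties.items():
                    mol.SetProp(key, str(values[i]))
            writer.write(mol)
    finally:
        writer.close()
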