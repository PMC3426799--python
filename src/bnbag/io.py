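"""Readers and writers: BIF networks and delimited-text data tables.

BIF (Bayesian Interchange Format) is the plain-text format most discrete
network repositories use.  The subset handled here covers the standard
``network``, ``variable`` and ``probability`` blocks with discrete
variables; properties are ignored on read.  Parent configurations in
``probability`` blocks are matched by state label, so files written by
other tools in a different row order load correctly.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BayesianNetwork,
    ConditionalTable,
    DataTable,
    NetworkStructure,
    VariableSpec,
)

__all__ = ["write_bif", "read_bif", "write_data_csv", "read_data_csv"]

_VAR_RE = re.compile(
    r"variable\s+(\S+)\s*\{[^}]*?type\s+discrete\s*\[\s*(\d+)\s*\]\s*\{([^}]*)\}", re.S
)
_PROB_RE = re.compile(r"probability\s*\(([^)]*)\)\s*\{(.*?)\}", re.S)


def write_bif(bn: BayesianNetwork, path: str | Path, name: str = "network") -> None:
    """Write a network as BIF. Probabilities use ``repr`` so reads round-trip."""
    s = bn.structure
    lines = [f"network {name} {{", "}"]
    for v in s.variables:
        lines.append(f"variable {v.name} {{")
        lines.append(
            f"  type discrete [ {v.arity} ] {{ " + ", ".join(v.states) + " };"
        )
        lines.append("}")
    for i, v in enumerate(s.variables):
        ps = s.parents[i]
        table = bn.tables[i].table
        if not ps:
            lines.append(f"probability ( {v.name} ) {{")
            lines.append("  table " + ", ".join(repr(float(x)) for x in table[0]) + ";")
        else:
            pnames = ", ".join(s.variables[p].name for p in ps)
            lines.append(f"probability ( {v.name} | {pnames} ) {{")
            # enumerate parent configs in mixed-radix order (last parent fastest)
            arities = [s.variables[p].arity for p in ps]
            for j in range(table.shape[0]):
                cfg, rem = [], j
                for a in reversed(arities):
                    cfg.append(rem % a)
                    rem //= a
                cfg = cfg[::-1]
                labels = ", ".join(
                    s.variables[p].states[k] for p, k in zip(ps, cfg)
                )
                row = ", ".join(repr(float(x)) for x in table[j])
                lines.append(f"  ({labels}) {row};")
        lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bif(path: str | Path) -> BayesianNetwork:
    """Parse a BIF file into a :class:`BayesianNetwork`."""
    text = Path(path).read_text()
    text = re.sub(r"//[^\n]*", "", text)  # strip line comments

    variables: list[VariableSpec] = []
    for m in _VAR_RE.finditer(text):
        name, arity, states = m.group(1), int(m.group(2)), m.group(3)
        labels = tuple(s.strip() for s in states.split(",") if s.strip())
        if len(labels) != arity:
            raise ValueError(f"variable {name}: {arity} states declared, {len(labels)} listed")
        variables.append(VariableSpec(name, labels))
    if not variables:
        raise ValueError(f"no variable blocks found in {path}")
    index = {v.name: i for i, v in enumerate(variables)}

    parents: list[tuple[int, ...]] = [()] * len(variables)
    raw_tables: dict[int, tuple[list[int], np.ndarray]] = {}
    for m in _PROB_RE.finditer(text):
        header, body = m.group(1), m.group(2)
        if "|" in header:
            child_s, parent_s = header.split("|")
            pnames = [p.strip() for p in parent_s.split(",") if p.strip()]
        else:
            child_s, pnames = header, []
        child = index[child_s.strip()]
        pidx = [index[p] for p in pnames]
        parents[child] = tuple(sorted(pidx))
        arities = [variables[p].arity for p in pidx]
        q = int(np.prod(arities)) if pidx else 1
        r = variables[child].arity
        table = np.full((q, r), np.nan)
        if not pidx:
            nums = re.search(r"table([^;]*);", body)
            if nums is None:
                raise ValueError(f"no table entry for root variable {child_s.strip()}")
            table[0] = [float(x) for x in nums.group(1).replace(",", " ").split()]
        else:
            # label order in the file may differ from our sorted-parent order
            order = np.argsort(pidx, kind="stable")
            sorted_p = [pidx[k] for k in order]
            for row_m in re.finditer(r"\(([^)]*)\)\s*([^;]*);", body):
                labels = [s.strip() for s in row_m.group(1).split(",")]
                states = [
                    variables[p].states.index(lab) for p, lab in zip(pidx, labels)
                ]
                j = _mixed_radix(
                    [states[k] for k in order], [variables[p].arity for p in sorted_p]
                )
                table[j] = [float(x) for x in row_m.group(2).replace(",", " ").split()]
        if np.isnan(table).any():
            raise ValueError(f"incomplete probability block for {child_s.strip()}")
        raw_tables[child] = (pidx, table)

    structure = NetworkStructure(tuple(variables), tuple(parents))
    tables = []
    for i in range(len(variables)):
        if i not in raw_tables:
            raise ValueError(f"no probability block for variable {variables[i].name}")
        tables.append(ConditionalTable(i, raw_tables[i][1]))
    return BayesianNetwork(structure, tuple(tables))


def _mixed_radix(digits: list[int], radices: list[int]) -> int:
    j = 0
    for d, r in zip(digits, radices):
        j = j * r + d
    return j


def write_data_csv(data: DataTable, path: str | Path, labels: bool = True) -> None:
    """Write a data table as CSV with a header of variable names."""
    cols = {}
    for i, v in enumerate(data.variables):
        col = data.values[:, i]
        cols[v.name] = [v.states[k] for k in col] if labels else col
    pd.DataFrame(cols).to_csv(path, index=False)


def read_data_csv(
    path: str | Path,
    network: BayesianNetwork | None = None,
    sep: str = ",",
) -> DataTable:
    """Read a delimited data table with a header row of variable names.

    If ``network`` is given, columns are matched to its variables by name
    and string states are mapped by the network's label order.  Otherwise
    integer columns are taken as 0-based state indices and string columns
    are mapped by sorted unique label.  Missing values are rejected: the
    learning machinery assumes complete data.
    """
    df = pd.read_csv(path, sep=sep)
    if df.isna().any().any():
        raise ValueError("data contains missing values; complete data is required")
    if network is not None:
        specs = network.structure.variables
        missing = [v.name for v in specs if v.name not in df.columns]
        if missing:
            raise ValueError(f"data lacks columns for variables: {missing}")
        values = np.zeros((len(df), len(specs)), dtype=np.int64)
        for i, v in enumerate(specs):
            col = df[v.name]
            if col.dtype.kind in "iu":
                values[:, i] = col.to_numpy()
            else:
                lut = {s: k for k, s in enumerate(v.states)}
                try:
                    values[:, i] = [lut[str(x)] for x in col]
                except KeyError as e:
                    raise ValueError(f"unknown state {e} for variable {v.name}") from e
        return DataTable(tuple(specs), values)
    specs = []
    values = np.zeros((len(df), df.shape[1]), dtype=np.int64)
    for i, name in enumerate(df.columns):
        col = df[name]
        if col.dtype.kind in "iu":
            arity = int(col.max()) + 1
            states = tuple(str(k) for k in range(max(arity, 2)))
            values[:, i] = col.to_numpy()
        else:
            labels_sorted = sorted(str(x) for x in col.unique())
            if len(labels_sorted) < 2:
                labels_sorted = labels_sorted + ["__other__"]
            lut = {s: k for k, s in enumerate(labels_sorted)}
            states = tuple(labels_sorted)
            values[:, i] = [lut[str(x)] for x in col]
        specs.append(VariableSpec(str(name), states))
    return DataTable(tuple(specs), values)
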