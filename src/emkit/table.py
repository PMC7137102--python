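"""In-memory typed tabular metadata.

A :class:`Table` is an ordered list of typed :class:`Column` definitions plus
an ordered list of row tuples.  Cells are either a value of the column's type
or the explicit :data:`MISSING` marker (the STAR "." / "?" tokens map to it).
Row-level operations — filtering with a small comparison/boolean expression
grammar, stable sorting, column arithmetic-free statistics — cover the
metadata manipulations EM practitioners otherwise reach for awk to do.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass
from typing import Callable, Iterable, List, NamedTuple, Optional, Sequence, Tuple

from .errors import TableError


class _Missing:
    """Singleton marker for an absent cell value."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()

CTYPES = ("int", "float", "string", "bool")

_PY_OF_CTYPE = {"int": int, "float": float, "string": str, "bool": bool}


@dataclass(frozen=True)
class Column:
    """A named, typed column.  Names are non-empty and whitespace-free."""

    name: str
    ctype: str

    def __post_init__(self) -> None:
        if not self.name or any(c.isspace() for c in self.name):
            raise TableError(f"invalid column name {self.name!r}")
        if self.ctype not in CTYPES:
            raise TableError(f"unknown column type {self.ctype!r}")

    def coerce(self, value):
        """Validate/convert one cell value; MISSING passes through."""
        if value is MISSING:
            return MISSING
        if self.ctype == "int":
            if isinstance(value, bool) or not isinstance(value, int):
                raise TableError(f"column {self.name}: {value!r} is not int")
            return int(value)
        if self.ctype == "float":
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise TableError(f"column {self.name}: {value!r} is not float")
            return float(value)
        if self.ctype == "bool":
            if not isinstance(value, bool):
                raise TableError(f"column {self.name}: {value!r} is not bool")
            return value
        if not isinstance(value, str):
            raise TableError(f"column {self.name}: {value!r} is not string")
        return value


class TableStats(NamedTuple):
    count: int
    min: float
    max: float
    mean: float
    std: float


class Table:
    """Ordered typed columns + ordered rows of values.

    All operations are out-of-place and return new tables.
    """

    def __init__(self, columns: Sequence[Column],
                 rows: Optional[Iterable[Sequence]] = None) -> None:
        cols = list(columns)
        names = [c.name for c in cols]
        if len(set(names)) != len(names):
            raise TableError("duplicate column names")
        self._columns: Tuple[Column, ...] = tuple(cols)
        self._index = {c.name: i for i, c in enumerate(cols)}
        self._rows: List[tuple] = []
        for row in rows or ():
            self._append(row)

    def _append(self, row: Sequence) -> None:
        row = tuple(row)
        if len(row) != len(self._columns):
            raise TableError(
                f"row has {len(row)} values for {len(self._columns)} columns"
            )
        self._rows.append(tuple(c.coerce(v) for c, v in zip(self._columns, row)))

    # -- introspection ----------------------------------------------------
    @property
    def columns(self) -> Tuple[Column, ...]:
        return self._columns

    @property
    def column_names(self) -> Tuple[str, ...]:
        return tuple(c.name for c in self._columns)

    @property
    def rows(self) -> Tuple[tuple, ...]:
        return tuple(self._rows)

    @property
    def n_rows(self) -> int:
        return len(self._rows)

    def column(self, name: str) -> Column:
        try:
            return self._columns[self._index[name]]
        except KeyError:
            raise TableError(f"unknown column {name!r}") from None

    def values(self, name: str) -> list:
        i = self._column_pos(name)
        return [r[i] for r in self._rows]

    def _column_pos(self, name: str) -> int:
        if name not in self._index:
            raise TableError(f"unknown column {name!r}")
        return self._index[name]

    def __eq__(self, other) -> bool:
        return (isinstance(other, Table)
                and self._columns == other._columns
                and self._rows == other._rows)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Table({len(self._columns)} cols x {len(self._rows)} rows)"

    # -- column operations ------------------------------------------------
    def with_row(self, row: Sequence) -> "Table":
        out = Table(self._columns, self._rows)
        out._append(row)
        return out

    def add_column(self, col: Column, default=MISSING) -> "Table":
        if col.name in self._index:
            raise TableError(f"duplicate column name {col.name!r}")
        default = col.coerce(default)
        rows = [r + (default,) for r in self._rows]
        return Table(list(self._columns) + [col], rows)

    def drop_column(self, name: str) -> "Table":
        i = self._column_pos(name)
        cols = [c for j, c in enumerate(self._columns) if j != i]
        rows = [r[:i] + r[i + 1:] for r in self._rows]
        return Table(cols, rows)

    def select(self, names: Sequence[str]) -> "Table":
        idx = [self._column_pos(n) for n in names]
        cols = [self._columns[i] for i in idx]
        rows = [tuple(r[i] for i in idx) for r in self._rows]
        return Table(cols, rows)

    # -- row operations ---------------------------------------------------
    def filter(self, expr: str) -> "Table":
        pred = compile_filter(expr, self)
        return Table(self._columns, [r for r in self._rows if pred(r)])

    def sort(self, key: str, ascending: bool = True) -> "Table":
        i = self._column_pos(key)
        col = self._columns[i]
        if col.ctype == "bool":
            raise TableError(f"column {key!r} is not orderable")

        # MISSING sorts after every real value regardless of direction;
        # sorted() is stable in both directions, so ties keep input order.
        present = [j for j, r in enumerate(self._rows) if r[i] is not MISSING]
        absent = [j for j, r in enumerate(self._rows) if r[i] is MISSING]
        order = sorted(present, key=lambda j: self._rows[j][i],
                       reverse=not ascending)
        return Table(self._columns, [self._rows[j] for j in order + absent])

    def stats(self, key: str) -> TableStats:
        i = self._column_pos(key)
        col = self._columns[i]
        if col.ctype not in ("int", "float"):
            raise TableError(f"column {key!r} is not numeric")
        vals = [float(r[i]) for r in self._rows if r[i] is not MISSING]
        n = len(vals)
        if n == 0:
            raise TableError(f"column {key!r} has no non-missing values")
        mean = math.fsum(vals) / n
        var = math.fsum((v - mean) ** 2 for v in vals) / n  # population
        return TableStats(n, min(vals), max(vals), mean, math.sqrt(var))


# ---------------------------------------------------------------------------
# Filter expression grammar: comparisons over columns and literals combined
# with and/or/not and parentheses.  Parsed once per call via the Python ast.
# ---------------------------------------------------------------------------

_CMP_OPS = {
    ast.Eq: "==", ast.NotEq: "!=", ast.Lt: "<", ast.LtE: "<=",
    ast.Gt: ">", ast.GtE: ">=",
}

_ORDERED = (ast.Lt, ast.LtE, ast.Gt, ast.GtE)


def compile_filter(expr: str, table: Table) -> Callable[[tuple], bool]:
    """Compile a filter expression into a per-row predicate.

    Comparisons involving a MISSING cell are false, so ``expr`` and
    ``not (expr)`` always partition the rows.
    """
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as e:
        raise TableError(f"bad filter expression: {e.msg}") from None
    pos = {c.name: i for i, c in enumerate(table.columns)}
    ctypes = {c.name: c.ctype for c in table.columns}

    def build(node) -> Callable[[tuple], object]:
        if isinstance(node, ast.Expression):
            return build(node.body)
        if isinstance(node, ast.BoolOp):
            parts = [build(v) for v in node.values]
            if isinstance(node.op, ast.And):
                return lambda r: all(p(r) for p in parts)
            return lambda r: any(p(r) for p in parts)
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Not):
            inner = build(node.operand)
            return lambda r: not inner(r)
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
            inner = build(node.operand)
            return lambda r: -inner(r)  # numeric literal negation
        if isinstance(node, ast.Compare):
            operands = [build(v) for v in [node.left] + node.comparators]
            ops = node.ops
            for op in ops:
                if type(op) not in _CMP_OPS:
                    raise TableError("unsupported comparison operator")

            def run(r, operands=operands, ops=ops):
                vals = [f(r) for f in operands]
                for a, op, b in zip(vals, ops, vals[1:]):
                    if not _compare(a, op, b):
                        return False
                return True

            return run
        if isinstance(node, ast.Name):
            if node.id not in pos:
                raise TableError(f"unknown column {node.id!r}")
            i = pos[node.id]
            return lambda r: r[i]
        if isinstance(node, ast.Constant) and isinstance(
                node.value, (int, float, str, bool)):
            v = node.value
            return lambda r: v
        raise TableError("unsupported syntax in filter expression")

    def _compare(a, op, b) -> bool:
        if a is MISSING or b is MISSING:
            return False
        a_num = isinstance(a, (int, float)) and not isinstance(a, bool)
        b_num = isinstance(b, (int, float)) and not isinstance(b, bool)
        if isinstance(op, _ORDERED):
            if a_num != b_num or isinstance(a, bool) or isinstance(b, bool):
                if not (a_num and b_num) and not (
                        isinstance(a, str) and isinstance(b, str)):
                    raise TableError(
                        f"cannot order {type(a).__name__} against "
                        f"{type(b).__name__}"
                    )
        table_ops = {
            "==": lambda x, y: x == y, "!=": lambda x, y: x != y,
            "<": lambda x, y: x < y, "<=": lambda x, y: x <= y,
            ">": lambda x, y: x > y, ">=": lambda x, y: x >= y,
        }
        return table_ops[_CMP_OPS[type(op)]](a, b)

    body = build(tree)

    # reject non-boolean top level like a bare column name of numeric type?
    # Accepted: truthiness of the value, documented behaviour.
    def pred(row: tuple) -> bool:
        return bool(body(row))

    # fail fast on unknown columns even for empty tables
    _ = ctypes
    return pred


# Spec-level operation aliases -------------------------------------------

def table_add_column(t: Table, col: Column, default=MISSING) -> Table:
    return t.add_column(col, default)


def table_filter(t: Table, expr: str) -> Table:
    return t.filter(expr)


def table_sort(t: Table, key: str, ascending: bool = True) -> Table:
    return t.sort(key, ascending)


def table_stats(t: Table, key: str) -> TableStats:
    return t.stats(key)
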