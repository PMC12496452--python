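"""Response-matrix container and delimited-text I/O.

Persons are rows, items are columns.  Missing responses are stored as -1
internally; any non-missing entry is 0 or 1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ItemParams2PL, LMPAParams

__all__ = ["ResponseMatrix", "read_responses", "ParseError",
           "read_item_params", "write_item_params"]

MISSING = -1
DEFAULT_MISSING_CODES = frozenset({"", "NA", "-9", "."})


class ParseError(ValueError):
    pass


class ResponseMatrix:
    """N x n dichotomous responses with an explicit missingness mask."""

    def __init__(self, data, item_ids=None, person_ids=None):
        data = np.asarray(data)
        if data.ndim != 2:
            raise ValueError("response data must be 2-dimensional")
        data = data.astype(np.int8, copy=True)
        bad = ~np.isin(data, (MISSING, 0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(f"invalid response value {data[r, c]} at row {r}, column {c}")
        self.data = data
        N, n = data.shape
        self.item_ids = list(item_ids) if item_ids is not None else [f"item_{i+1}" for i in range(n)]
        self.person_ids = list(person_ids) if person_ids is not None else [f"p_{j+1}" for j in range(N)]
        if len(self.item_ids) != n:
            raise ValueError("item_ids length does not match column count")
        if len(set(self.item_ids)) != n:
            raise ValueError("duplicate item ids")
        if len(self.person_ids) != N:
            raise ValueError("person_ids length does not match row count")

    @property
    def N(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean N x n validity mask (True where a response is observed)."""
        return self.data != MISSING

    @property
    def n_valid(self) -> np.ndarray:
        """Per-item count of valid responses N_i."""
        return self.mask.sum(axis=0)

    @property
    def n_correct(self) -> np.ndarray:
        """Per-item count of correct responses N_i1."""
        return (self.data == 1).sum(axis=0)

    def indicator_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Float indicator matrices (correct, incorrect); missing rows are 0 in both."""
        return (self.data == 1).astype(float), (self.data == 0).astype(float)

    def with_data(self, data) -> "ResponseMatrix":
        return ResponseMatrix(data, item_ids=self.item_ids, person_ids=self.person_ids)

    def __eq__(self, other):
        return (
            isinstance(other, ResponseMatrix)
            and np.array_equal(self.data, other.data)
            and self.item_ids == other.item_ids
        )

    def to_csv(self, path, delimiter=",", missing_code="NA", header=True):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter=delimiter)
            if header:
                w.writerow(self.item_ids)
            for row in self.data:
                w.writerow([missing_code if v == MISSING else int(v) for v in row])


def read_responses(path, missing_codes=DEFAULT_MISSING_CODES, delimiter=",",
                   transpose=False) -> ResponseMatrix:
    """Read a delimited 0/1 response matrix (persons as rows, items as columns).

    A header row of item ids is auto-detected: if any token of the first row
    is neither 0, 1, nor a missing code, the row is treated as a header.
    Unparseable cells raise :class:`ParseError` naming the offending cell.
    """
    missing_codes = {str(m) for m in missing_codes}
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter=delimiter) if row]
    if not rows:
        raise ParseError(f"{path}: empty file")
    tokens_ok = all(t.strip() in missing_codes | {"0", "1"} for t in rows[0])
    item_ids = None
    if not tokens_ok:
        item_ids = [t.strip() for t in rows[0]]
        if len(set(item_ids)) != len(item_ids):
            raise ParseError(f"{path}: duplicate item ids in header")
        rows = rows[1:]
    n = len(rows[0]) if rows else 0
    data = np.empty((len(rows), n), dtype=np.int8)
    for r, row in enumerate(rows):
        if len(row) != n:
            raise ParseError(f"{path}: row {r+1} has {len(row)} fields, expected {n}")
        for c, tok in enumerate(row):
            tok = tok.strip()
            if tok in missing_codes:
                data[r, c] = MISSING
            elif tok in ("0", "1"):
                data[r, c] = int(tok)
            else:
                raise ParseError(f"{path}: invalid token {tok!r} at row {r+1}, column {c+1}")
    if transpose:
        data = data.T
        item_ids = None
    return ResponseMatrix(data, item_ids=item_ids)


# --- item-parameter files -------------------------------------------------

def write_item_params(path, params, item_ids=None, delimiter=","):
    """Write item parameters (2PL or LMPA) to delimited text.

    Columns: item_id, model, a, b for 2PL rows; LMPA rows carry k, g, omega,
    delta and alpha_s / tau_s columns instead of a, b.  Values round-trip at
    10 decimal digits.
    """
    params = list(params)
    if item_ids is None:
        item_ids = [f"item_{i+1}" for i in range(len(params))]
    kmax = max((p.k for p in params if isinstance(p, LMPAParams)), default=0)
    cols = ["item_id", "model", "a", "b", "k", "g", "omega", "delta"]
    cols += [f"alpha{s+1}" for s in range(kmax)] + [f"tau{s+1}" for s in range(kmax)]
    fmt = lambda v: "" if v is None else f"{float(v):.10f}"
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(cols)
        for iid, p in zip(item_ids, params):
            if isinstance(p, ItemParams2PL):
                row = [iid, "2PL", fmt(p.slope), fmt(p.difficulty)] + [""] * (4 + 2 * kmax)
            else:
                row = [iid, "LMPA", "", "", str(p.k), fmt(p.g), fmt(p.omega), fmt(p.delta)]
                row += [fmt(a) for a in p.alpha] + [""] * (kmax - p.k)
                row += [fmt(t) for t in p.tau] + [""] * (kmax - p.k)
            w.writerow(row)


def read_item_params(path, delimiter=","):
    """Read an item-parameter file written by :func:`write_item_params`.

    Returns ``(params, item_ids)`` where each entry of ``params`` is an
    :class:`ItemParams2PL` or :class:`LMPAParams`.
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype=str)
    if df["item_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate item ids")
    params, ids = [], []
    for _, row in df.iterrows():
        ids.append(row["item_id"])
        if row["model"] == "2PL":
            params.append(ItemParams2PL(slope=float(row["a"]), difficulty=float(row["b"])))
        elif row["model"] == "LMPA":
            k = int(row["k"])
            alpha = tuple(float(row[f"alpha{s+1}"]) for s in range(k))
            tau = tuple(float(row[f"tau{s+1}"]) for s in range(k))
            params.append(LMPAParams(k=k, g=float(row["g"]), omega=float(row["omega"]),
                                     delta=float(row["delta"]), alpha=alpha, tau=tau))
        else:
            raise ParseError(f"{path}: unknown model {row['model']!r} for {row['item_id']}")
    return params, ids
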