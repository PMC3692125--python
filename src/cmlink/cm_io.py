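"""Reading and writing covariance model files.

Two ASCII dialects are supported, matching the two generations of the Infernal
CM flatfile layout:

* ``INFERNAL_1_0`` — header line ``INFERNAL-1 [1.0]``; emission fields are
  log-odds bit scores against the record's null model.
* ``INFERNAL_1_1`` — header line ``INFERNAL1/a [1.1]``; emission fields are
  log2 probabilities.

Both dialects share the record skeleton: keyword header lines (NAME, ACC,
STATES, NODES, CLEN, NULL, ...), a ``MODEL:`` section of node lines
(``[ MATL 3 ]``) each followed by its state lines, and a ``//`` terminator.
Files may hold several concatenated records (Rfam ships its whole database as
one flatfile). Transition fields are log2 transition probabilities in both
dialects; the NULL line stores log2(4p) per nucleotide; the marker ``*``
denotes impossibility and maps to the absorbing sentinel.

Whatever a dialect stores on disk, the in-memory model is dialect-agnostic:
emissions are converted to log-odds bits against the parsed null model on
read, so downstream scoring never needs to know where a model came from.
Header lines that scoring does not consume (calibration statistics, build
provenance, checksums) are preserved verbatim for round-trip but not
interpreted.

State line layout::

    <type> <index> <cfirst> <cnum> <cnum transition scores> <emission scores>

except for B states, whose two integer fields are the left and right child
state indices, and E states, which carry ``-1 0``.
"""

from __future__ import annotations

import shutil
import subprocess
from pathlib import Path

import numpy as np

from .model import (
    EMISSION_ARITY,
    NEG_INF,
    CovarianceModel,
    Dialect,
    Node,
    NodeType,
    State,
    StateType,
    validate_model,
)

_HEADERS = {
    Dialect.INFERNAL_1_0: "INFERNAL-1 [1.0]",
    Dialect.INFERNAL_1_1: "INFERNAL1/a [1.1]",
}

_KNOWN_KEYS = {"NAME", "ACC", "STATES", "NODES", "CLEN", "ALPH", "NULL"}


class CMFormatError(ValueError):
    """Malformed CM document (bad header, unknown state type, ...)."""


class CMValidationError(ValueError):
    """Structurally invalid model (bad indices, unnormalized null, ...)."""


def _fmt(score: float) -> str:
    return "*" if score == NEG_INF else f"{score:.5f}"


def _num(token: str, line_no: int) -> float:
    if token == "*":
        return NEG_INF
    try:
        return float(token)
    except ValueError:
        raise CMFormatError(f"line {line_no}: expected a score, got {token!r}") from None


def _pair_log_null(log_null: np.ndarray) -> np.ndarray:
    return np.add.outer(log_null, log_null).reshape(16)


def write_cm_file(models: list[CovarianceModel], dialect: Dialect) -> str:
    """Serialize models into a (possibly multi-record) CM document."""
    out: list[str] = []
    for model in models:
        log_null = np.log2(np.asarray(model.null, dtype=float))
        out.append(_HEADERS[dialect])
        out.append(f"NAME     {model.name}")
        if model.accession:
            out.append(f"ACC      {model.accession}")
        out.append(f"STATES   {len(model.states)}")
        out.append(f"NODES    {len(model.nodes)}")
        out.append(f"CLEN     {model.consensus_length}")
        out.append("ALPH     RNA")
        out.append(
            "NULL     " + " ".join(f"{v + 2.0:.7f}" for v in log_null)
        )
        out.extend(model.extras)
        out.append("MODEL:")
        for node in model.nodes:
            out.append(f"\t\t\t\t[ {node.node_type.value} {node.index} ]")
            for si in node.state_indices:
                st = model.states[si]
                fields = [f"{st.state_type.value:>6}", f"{st.index:5d}"]
                if st.state_type is StateType.B:
                    left, right = st.bif_children
                    fields += [f"{left:5d}", f"{right:5d}"]
                elif st.state_type is StateType.E:
                    fields += [f"{-1:5d}", f"{0:5d}"]
                else:
                    children = sorted(st.transitions)
                    cfirst, cnum = children[0], len(children)
                    if children != list(range(cfirst, cfirst + cnum)):
                        raise CMValidationError(
                            f"state {st.index}: transition targets are not a "
                            "contiguous range and cannot be serialized"
                        )
                    fields += [f"{cfirst:5d}", f"{cnum:5d}"]
                    fields += [_fmt(st.transitions[c]) for c in children]
                if len(st.emissions):
                    if dialect is Dialect.INFERNAL_1_1:
                        base = (
                            _pair_log_null(log_null)
                            if st.state_type is StateType.MP
                            else log_null
                        )
                        vals = [
                            NEG_INF if e == NEG_INF else e + b
                            for e, b in zip(st.emissions, base)
                        ]
                    else:
                        vals = list(st.emissions)
                    fields += [_fmt(v) for v in vals]
                out.append(" ".join(fields))
        out.append("//")
    return "\n".join(out) + ("\n" if out else "")


def parse_cm_file(text: str) -> list[CovarianceModel]:
    """Parse one or more concatenated CM records.

    Raises :class:`CMFormatError` for malformed documents (naming the line)
    and :class:`CMValidationError` when a record parses but violates a model
    invariant.
    """
    lines = text.splitlines()
    models: list[CovarianceModel] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if line == _HEADERS[Dialect.INFERNAL_1_0]:
            dialect = Dialect.INFERNAL_1_0
        elif line == _HEADERS[Dialect.INFERNAL_1_1]:
            dialect = Dialect.INFERNAL_1_1
        elif line.startswith("INFERNAL"):
            raise CMFormatError(f"line {i + 1}: unrecognized CM header {line!r}")
        else:
            raise CMFormatError(
                f"line {i + 1}: expected an INFERNAL header, got {line!r}"
            )
        model, i = _parse_record(lines, i + 1, dialect)
        models.append(model)
    return models


def _parse_record(lines: list[str], i: int, dialect: Dialect):
    name = None
    accession = None
    n_states = n_nodes = clen = None
    null = None
    extras: list[str] = []

    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line == "MODEL:":
            break
        key, _, rest = line.partition(" ")
        rest = rest.strip()
        if key == "NAME":
            name = rest
        elif key == "ACC":
            accession = rest
        elif key == "STATES":
            n_states = int(rest)
        elif key == "NODES":
            n_nodes = int(rest)
        elif key == "CLEN":
            clen = int(rest)
        elif key == "ALPH":
            if rest.upper() not in ("RNA", "DNA"):
                raise CMFormatError(f"line {i}: unsupported alphabet {rest!r}")
        elif key == "NULL":
            vals = [_num(t, i) for t in rest.split()]
            if len(vals) != 4:
                raise CMFormatError(f"line {i}: NULL needs 4 values, got {len(vals)}")
            null = np.exp2(np.array(vals)) / 4.0
            # absorb the rounding of the stored log2 values; anything beyond
            # print precision is a genuinely bad null and is left for
            # validation to flag
            if abs(float(null.sum()) - 1.0) < 1e-3:
                null = null / null.sum()
        else:
            extras.append(line)
    else:
        raise CMFormatError(f"line {i}: record ended before MODEL: section")

    if name is None:
        raise CMFormatError(f"line {i}: record has no NAME line")
    if null is None:
        raise CMFormatError(f"line {i}: record has no NULL line")
    log_null = np.log2(null)
    pair_base = _pair_log_null(log_null)

    states: list[State] = []
    nodes: list[Node] = []
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line == "//":
            break
        if line.startswith("["):
            toks = line.strip("[] \t").split()
            if len(toks) != 2 or toks[0] not in NodeType.__members__:
                raise CMFormatError(f"line {i}: malformed node line {line!r}")
            nodes.append(Node(index=int(toks[1]), node_type=NodeType[toks[0]]))
            continue
        toks = line.split()
        if toks[0] not in StateType.__members__:
            raise CMFormatError(f"line {i}: unknown state type {toks[0]!r}")
        if not nodes:
            raise CMFormatError(f"line {i}: state line before any node line")
        stype = StateType[toks[0]]
        try:
            idx = int(toks[1])
            f1, f2 = int(toks[2]), int(toks[3])
        except (IndexError, ValueError):
            raise CMFormatError(f"line {i}: malformed state line {line!r}") from None
        st = State(index=idx, state_type=stype, node_index=nodes[-1].index)
        pos = 4
        if stype is StateType.B:
            st.bif_children = (f1, f2)
        elif stype is not StateType.E:
            scores = [_num(t, i) for t in toks[pos : pos + f2]]
            if len(scores) != f2:
                raise CMFormatError(f"line {i}: expected {f2} transition scores")
            st.transitions = {f1 + k: s for k, s in enumerate(scores)}
            pos += f2
        arity = EMISSION_ARITY[stype]
        if arity:
            evals = [_num(t, i) for t in toks[pos : pos + arity]]
            if len(evals) != arity:
                raise CMFormatError(
                    f"line {i}: expected {arity} emission scores for {stype.value}"
                )
            if dialect is Dialect.INFERNAL_1_1:
                base = pair_base if stype is StateType.MP else log_null
                evals = [
                    NEG_INF if e == NEG_INF else e - b for e, b in zip(evals, base)
                ]
            st.emissions = np.array(evals)
        nodes[-1].state_indices.append(idx)
        states.append(st)

    model = CovarianceModel(
        name=name,
        accession=accession,
        states=states,
        nodes=nodes,
        null=null,
        dialect=dialect,
        consensus_length=clen if clen is not None else 0,
        extras=extras,
    )
    if n_states is not None and n_states != len(states):
        raise CMFormatError(
            f"record {name}: STATES says {n_states}, found {len(states)}"
        )
    if n_nodes is not None and n_nodes != len(nodes):
        raise CMFormatError(f"record {name}: NODES says {n_nodes}, found {len(nodes)}")
    diags = validate_model(model)
    if diags:
        raise CMValidationError(
            f"record {name}: invalid model: " + "; ".join(diags[:5])
        )
    return model, i


def read_cm_path(path: str | Path) -> list[CovarianceModel]:
    """Read all CM records from a file."""
    return parse_cm_file(Path(path).read_text())


def read_cm_directory(path: str | Path, pattern: str = "*.cm") -> list[CovarianceModel]:
    """Read every matching CM file in a directory, in sorted filename order.

    Unreadable files are skipped with their error recorded on the returned
    list's companion; use :func:`read_cm_directory_with_errors` for the errors.
    """
    models, _ = read_cm_directory_with_errors(path, pattern)
    return models


def read_cm_directory_with_errors(
    path: str | Path, pattern: str = "*.cm"
) -> tuple[list[CovarianceModel], list[str]]:
    models: list[CovarianceModel] = []
    errors: list[str] = []
    for f in sorted(Path(path).glob(pattern)):
        try:
            models.extend(read_cm_path(f))
        except (CMFormatError, CMValidationError, OSError) as exc:
            errors.append(f"{f.name}: {exc}")
    return models, errors


def build_from_stockholm(path: str | Path, cmbuild: str = "cmbuild") -> Path:
    """Convert a Stockholm alignment to a CM by invoking Infernal's cmbuild.

    This is an external-tool hook only: Stockholm alignments are never parsed
    here. Raises ``RuntimeError`` when cmbuild is not installed.
    """
    exe = shutil.which(cmbuild)
    if exe is None:
        raise RuntimeError(
            "Stockholm input requires Infernal: 'cmbuild' was not found on "
            "PATH. Install Infernal or supply a CM file instead."
        )
    path = Path(path)
    out = path.with_suffix(".cm")
    subprocess.run([exe, "-F", str(out), str(path)], check=True)
    return out
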