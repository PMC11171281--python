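"""Drop-in "external QM engine" facade: file protocol, TCP server, client.

An MD engine that can call an external QM program (the ORCA-style external
interface) writes a job directory with the ML geometry and the MM point
charges, invokes an executable, and reads energies and gradients back from
files.  This module pins a simplified dialect of that exchange:

``coords.xyz``
    Standard XYZ: atom count, comment line, then ``element x y z`` records
    in Å.
``pointcharges.pc``
    A count header line, then one ``q x y z`` record per MM charge (charge
    in e, coordinates in Å).
``emle.engrad``
    Reply: atom count line, total energy line (hartree), then one ML
    gradient component per line (hartree/bohr, atom-major x y z).
``emle.pcgrad``
    Reply: charge count line, then one ``gx gy gz`` record per MM site
    (hartree/bohr).

Numbers are written with 16 significant digits in fixed scientific
notation, so replies are bit-stable across runs and round-trip through the
parser to better than 1e-12.

The server is a plain TCP socket service with newline-terminated framing:
``<MSGTYPE> <payload-length>\\n`` followed by the UTF-8 payload.  Message
types are ``RUN`` (payload = job directory; one calculation per request,
served strictly FIFO), ``PING`` and ``SHUTDOWN``.  Replies use the same
framing with types ``OK`` and ``ERROR``; a malformed message or a backend
exception produces an ``ERROR`` reply and leaves the server running.
"""

from __future__ import annotations

import socket
import traceback
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import yaml

from .calculator import EmbeddingMode, ToyBackend, total_energy
from .core_types import (
    BOHR_TO_ANGSTROM,
    EmleError,
    GlobalParams,
    MLRegion,
    MMEnvironment,
    read_parameter_file,
)

__all__ = [
    "EngineFormatError",
    "EngineRequest",
    "EngineReply",
    "CalculationConfig",
    "load_config",
    "parse_request",
    "write_request",
    "write_reply",
    "read_reply",
    "run_calculation",
    "EmleServer",
    "send_message",
    "run_client",
]

COORDS_FILE = "coords.xyz"
POINTCHARGES_FILE = "pointcharges.pc"
ENGRAD_FILE = "emle.engrad"
PCGRAD_FILE = "emle.pcgrad"

_FMT = "%23.16e"  # fixed-width scientific: bit-stable, >= 16 sig digits


class EngineFormatError(EmleError):
    """Malformed engine-protocol file (message carries file and line)."""


@dataclass
class EngineRequest:
    """A parsed engine job: geometry in bohr, charges in e."""

    job_dir: Path
    elements: Tuple[str, ...]
    ml_coords: np.ndarray
    mm_charges: np.ndarray
    mm_coords: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_charges(self) -> int:
        return int(self.mm_charges.shape[0])


@dataclass
class EngineReply:
    """Energy (hartree) and gradients (hartree/bohr) for one request."""

    energy: float
    grad_ml: np.ndarray
    grad_mm: np.ndarray


@dataclass
class CalculationConfig:
    """Server/CLI calculation settings (the key-value config file).

    Keys: ``backend`` (only ``toy`` ships), ``mode`` (one of the embedding
    modes), ``params`` (parameter file path), ``host``, ``port``.
    """

    backend: str = "toy"
    mode: str = "emle_total"
    params: Optional[str] = None
    host: str = "127.0.0.1"
    port: int = 10101

    def make_backend(self):
        if self.backend == "toy":
            return ToyBackend()
        raise EmleError(
            f"unknown backend {self.backend!r} (only 'toy' is bundled; "
            "external ML backends plug in via the library API)"
        )


def load_config(path: Union[str, Path]) -> CalculationConfig:
    """Load a YAML key-value config file."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise EmleError(f"config file {path} must hold a key-value mapping")
    known = {f for f in CalculationConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise EmleError(f"unknown config keys: {sorted(unknown)}")
    return CalculationConfig(**data)


# ---------------------------------------------------------------------------
# Request files
# ---------------------------------------------------------------------------


def _data_lines(path: Path):
    """(lineno, stripped line) for non-blank lines; tolerant of trailing
    whitespace and blank lines."""
    if not path.is_file():
        raise EngineFormatError(f"missing file: {path}")
    out = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line:
            out.append((lineno, line))
    return out


def _parse_xyz(path: Path):
    lines = _data_lines(path)
    if not lines:
        raise EngineFormatError(f"{path}: empty file")
    lineno0, header = lines[0]
    try:
        n = int(header.split()[0])
    except (ValueError, IndexError):
        raise EngineFormatError(
            f"{path}:{lineno0}: expected an atom count, got {header!r}"
        ) from None
    records = lines[1:]
    # a comment line is present in standard XYZ; detect and drop it
    if records and len(records) == n + 1:
        records = records[1:]
    if len(records) != n:
        raise EngineFormatError(
            f"{path}: count header says {n} atoms but found "
            f"{len(records)} records"
        )
    elements = []
    coords = np.empty((n, 3))
    for i, (lineno, line) in enumerate(records):
        tokens = line.split()
        if len(tokens) != 4:
            raise EngineFormatError(
                f"{path}:{lineno}: expected 'element x y z', got {line!r}"
            )
        try:
            coords[i] = [float(t) for t in tokens[1:]]
        except ValueError:
            raise EngineFormatError(
                f"{path}:{lineno}: non-numeric coordinate in {line!r}"
            ) from None
        elements.append(tokens[0])
    return tuple(elements), coords


def _parse_pointcharges(path: Path):
    lines = _data_lines(path)
    if not lines:
        raise EngineFormatError(f"{path}: empty file")
    lineno0, header = lines[0]
    try:
        n = int(header.split()[0])
    except (ValueError, IndexError):
        raise EngineFormatError(
            f"{path}:{lineno0}: expected a charge count, got {header!r}"
        ) from None
    records = lines[1:]
    if len(records) != n:
        bad = records[n][0] if len(records) > n else lineno0
        raise EngineFormatError(
            f"{path}: count header (line {lineno0}) says {n} charges but "
            f"found {len(records)} records (see line {bad})"
        )
    charges = np.empty(n)
    coords = np.empty((n, 3))
    for i, (lineno, line) in enumerate(records):
        tokens = line.split()
        if len(tokens) != 4:
            raise EngineFormatError(
                f"{path}:{lineno}: expected 'q x y z', got {line!r}"
            )
        try:
            vals = [float(t) for t in tokens]
        except ValueError:
            raise EngineFormatError(
                f"{path}:{lineno}: non-numeric field in {line!r}"
            ) from None
        charges[i] = vals[0]
        coords[i] = vals[1:]
    return charges, coords


def parse_request(job_dir: Union[str, Path]) -> EngineRequest:
    """Parse a job directory into an :class:`EngineRequest` (atomic units).

    Strict on counts, tolerant of blank lines and trailing whitespace.
    Errors name the offending file and line.
    """
    job_dir = Path(job_dir)
    elements, ml_ang = _parse_xyz(job_dir / COORDS_FILE)
    charges, mm_ang = _parse_pointcharges(job_dir / POINTCHARGES_FILE)
    return EngineRequest(
        job_dir=job_dir,
        elements=elements,
        ml_coords=ml_ang / BOHR_TO_ANGSTROM,
        mm_charges=charges,
        mm_coords=mm_ang / BOHR_TO_ANGSTROM,
    )


def write_request(
    job_dir: Union[str, Path],
    ml: MLRegion,
    mm: MMEnvironment,
    global_params: GlobalParams = GlobalParams(),
    params_file: str = "params.emle",
) -> Path:
    """Write a complete job directory (coords, point charges, parameters)
    for a region/environment pair.  Coordinates are converted to Å."""
    from .core_types import write_parameter_file

    job_dir = Path(job_dir)
    job_dir.mkdir(parents=True, exist_ok=True)
    ang = ml.coords * BOHR_TO_ANGSTROM
    lines = [str(ml.n_atoms), "synthetic emlekit job"]
    for el, xyz in zip(ml.elements, ang):
        lines.append(
            f"{el:<3s} " + " ".join(_FMT % v for v in xyz)
        )
    (job_dir / COORDS_FILE).write_text("\n".join(lines) + "\n")
    pc = [str(mm.n_charges)]
    for q, xyz in zip(mm.charges, mm.coords * BOHR_TO_ANGSTROM):
        pc.append(_FMT % q + " " + " ".join(_FMT % v for v in xyz))
    (job_dir / POINTCHARGES_FILE).write_text("\n".join(pc) + "\n")
    write_parameter_file(job_dir / params_file, ml.params, global_params)
    return job_dir


# ---------------------------------------------------------------------------
# Reply files
# ---------------------------------------------------------------------------


def write_reply(reply: EngineReply, job_dir: Union[str, Path]) -> None:
    """Write the engrad-style and point-charge-gradient reply files.

    Fixed format, 16 significant digits, bit-stable for identical input.
    Raises on non-finite values.
    """
    job_dir = Path(job_dir)
    grad_ml = np.asarray(reply.grad_ml, float)
    grad_mm = np.asarray(reply.grad_mm, float)
    if not (
        np.isfinite(reply.energy)
        and np.all(np.isfinite(grad_ml))
        and np.all(np.isfinite(grad_mm))
    ):
        raise EmleError("refusing to write non-finite reply values")
    lines = [str(grad_ml.shape[0]), _FMT % reply.energy]
    lines += [_FMT % v for v in grad_ml.ravel()]
    (job_dir / ENGRAD_FILE).write_text("\n".join(lines) + "\n")
    pc = [str(grad_mm.shape[0])]
    pc += [" ".join(_FMT % v for v in row) for row in grad_mm]
    (job_dir / PCGRAD_FILE).write_text("\n".join(pc) + "\n")


def read_reply(job_dir: Union[str, Path]) -> EngineReply:
    """Parse reply files back into an :class:`EngineReply`."""
    job_dir = Path(job_dir)
    lines = _data_lines(job_dir / ENGRAD_FILE)
    try:
        n = int(lines[0][1])
        energy = float(lines[1][1])
        comps = np.array([float(l) for _, l in lines[2:]])
    except (ValueError, IndexError):
        raise EngineFormatError(f"malformed {job_dir / ENGRAD_FILE}") from None
    if comps.size != 3 * n:
        raise EngineFormatError(
            f"{job_dir / ENGRAD_FILE}: expected {3 * n} gradient "
            f"components, found {comps.size}"
        )
    pc_lines = _data_lines(job_dir / PCGRAD_FILE)
    try:
        m = int(pc_lines[0][1])
        grad_mm = np.array(
            [[float(t) for t in l.split()] for _, l in pc_lines[1:]]
        ).reshape(-1, 3)
    except (ValueError, IndexError):
        raise EngineFormatError(f"malformed {job_dir / PCGRAD_FILE}") from None
    if grad_mm.shape[0] != m:
        raise EngineFormatError(
            f"{job_dir / PCGRAD_FILE}: count header says {m}, found "
            f"{grad_mm.shape[0]} records"
        )
    return EngineReply(energy, comps.reshape(n, 3), grad_mm)


# ---------------------------------------------------------------------------
# Calculation driver
# ---------------------------------------------------------------------------


def run_calculation(
    job_dir: Union[str, Path], config: CalculationConfig
) -> EngineReply:
    """Parse a job directory, run the calculation, write and return the
    reply.  This is the single code path used by both the server and the
    direct CLI, so the two produce identical reply bytes."""
    job_dir = Path(job_dir)
    request = parse_request(job_dir)
    params_path = (
        Path(config.params)
        if config.params
        else job_dir / "params.emle"
    )
    atoms, gp = read_parameter_file(params_path)
    if len(atoms) != request.n_atoms:
        raise EngineFormatError(
            f"parameter file has {len(atoms)} records for "
            f"{request.n_atoms} atoms"
        )
    for i, (p, el) in enumerate(zip(atoms, request.elements)):
        if p.element.lower() != el.lower():
            raise EngineFormatError(
                f"element mismatch at atom {i}: geometry says {el!r}, "
                f"parameters say {p.element!r}"
            )
    ml = MLRegion(request.ml_coords, atoms)
    mm = MMEnvironment(request.mm_charges, request.mm_coords)
    result = total_energy(
        ml, mm, config.make_backend(), EmbeddingMode.coerce(config.mode), gp
    )
    reply = EngineReply(result.e_total, result.grad_ml, result.grad_mm)
    write_reply(reply, job_dir)
    return reply


# ---------------------------------------------------------------------------
# TCP server and client
# ---------------------------------------------------------------------------


def _recv_exact(sock: socket.socket, n: int) -> bytes:
    buf = b""
    while len(buf) < n:
        chunk = sock.recv(n - len(buf))
        if not chunk:
            raise ConnectionError("connection closed mid-message")
        buf += chunk
    return buf


def _recv_message(sock: socket.socket) -> Tuple[str, str]:
    header = b""
    while not header.endswith(b"\n"):
        c = sock.recv(1)
        if not c:
            raise ConnectionError("connection closed before header")
        header += c
        if len(header) > 256:
            raise EngineFormatError("oversized message header")
    parts = header.decode("utf-8", "replace").strip().split()
    if len(parts) != 2:
        raise EngineFormatError(f"malformed header {header!r}")
    msgtype, length_s = parts
    try:
        length = int(length_s)
        if length < 0 or length > 10_000_000:
            raise ValueError
    except ValueError:
        raise EngineFormatError(
            f"bad payload length {length_s!r}"
        ) from None
    payload = _recv_exact(sock, length) if length else b""
    return msgtype, payload.decode("utf-8")


def _send_message(sock: socket.socket, msgtype: str, payload: str = "") -> None:
    data = payload.encode("utf-8")
    sock.sendall(f"{msgtype} {len(data)}\n".encode("utf-8") + data)


class EmleServer:
    """Single-threaded TCP calculation server (strict FIFO).

    One calculation per ``RUN`` request; the ``OK`` reply is sent only
    after the reply files exist, so a client that has received ``OK`` can
    safely read them.  Requests from any number of clients are serialized
    in accept order; no state is carried between requests.
    """

    def __init__(
        self,
        config: CalculationConfig,
        host: Optional[str] = None,
        port: Optional[int] = None,
    ):
        self.config = config
        self._sock = socket.create_server(
            (host or config.host, config.port if port is None else port)
        )
        self._sock.settimeout(0.5)
        self._running = False

    @property
    def address(self) -> Tuple[str, int]:
        return self._sock.getsockname()[:2]

    @property
    def port(self) -> int:
        return self.address[1]

    def serve_forever(self) -> None:
        """Accept and serve requests until a SHUTDOWN message arrives."""
        self._running = True
        try:
            while self._running:
                try:
                    conn, _ = self._sock.accept()
                except socket.timeout:
                    continue
                with conn:
                    self._handle(conn)
        finally:
            self._sock.close()

    def close(self) -> None:
        self._running = False

    def _handle(self, conn: socket.socket) -> None:
        try:
            msgtype, payload = _recv_message(conn)
        except (EngineFormatError, ConnectionError) as exc:
            try:
                _send_message(conn, "ERROR", f"bad message: {exc}")
            except OSError:
                pass
            return
        if msgtype == "PING":
            _send_message(conn, "OK", "pong")
        elif msgtype == "SHUTDOWN":
            _send_message(conn, "OK", "shutting down")
            self._running = False
        elif msgtype == "RUN":
            try:
                reply = run_calculation(payload.strip(), self.config)
            except Exception as exc:  # error reply, server stays up
                tb = traceback.format_exception_only(type(exc), exc)
                _send_message(conn, "ERROR", "".join(tb).strip())
                return
            _send_message(conn, "OK", _FMT % reply.energy)
        else:
            _send_message(conn, "ERROR", f"unknown message type {msgtype!r}")


def send_message(
    host: str, port: int, msgtype: str, payload: str = "", timeout: float = 60.0
) -> Tuple[str, str]:
    """Send one framed message and return ``(status, payload)``."""
    with socket.create_connection((host, port), timeout=timeout) as sock:
        _send_message(sock, msgtype, payload)
        return _recv_message(sock)


def run_client(
    job_dir: Union[str, Path],
    host: str,
    port: int,
    timeout: float = 300.0,
) -> EngineReply:
    """The thin "fake QM executable" client: forward the job directory to
    the server, block until the reply files exist, and return the parsed
    reply.  Raises :class:`EmleError` on an ERROR reply."""
    job_dir = Path(job_dir).resolve()
    status, payload = send_message(
        host, port, "RUN", str(job_dir), timeout=timeout
    )
    if status != "OK":
        raise EmleError(f"server error: {payload}")
    return read_reply(job_dir)
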