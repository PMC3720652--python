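"""Byte-offset scatter/gather execution over large sequence files.

A large read or alignment file is decomposed into fixed-size byte chunks.
Each chunk becomes one task of an emulated array job; tasks run on a local
worker pool, and their part results are merged afterwards. A plugin supplies
the four functions of the contract (split, count, process, combine); the
engine guarantees that a combined result is produced even when some tasks
fail, covering exactly the chunks that could be processed.
"""

from __future__ import annotations

import json
import math
import os
import time
from collections import deque
from concurrent.futures import ThreadPoolExecutor
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Callable, Sequence

#: Default chunk size in bytes (~50 MB), the production value used for
#: splitting read files into array-job tasks.
DEFAULT_CHUNK_SIZE = 50_000_000

#: Maximum number of part files merged in one pass of the recursive
#: concatenation, bounding the number of simultaneously open parts.
DEFAULT_FAN_IN = 100

STATUS_PHASES = ("submitted", "started", "step", "failed", "completed")


class RecordBoundaryError(ValueError):
    """A record at a chunk boundary could not be parsed."""

    def __init__(self, path: Any, offset: int, message: str):
        self.offset = offset
        super().__init__(f"{path}: malformed record at byte {offset}: {message}")


@dataclass(frozen=True)
class ChunkTask:
    """One task of the array job: a half-open byte range given inclusively."""

    task_id: int  # 1-based
    start: int
    end: int  # inclusive


@dataclass(frozen=True)
class ChunkPlan:
    """Byte-offset decomposition of an input file into array-job tasks."""

    file_size: int
    chunk_size: int
    tasks: tuple[ChunkTask, ...]

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)


def chunk_bounds(task_id: int, chunk_size: int = DEFAULT_CHUNK_SIZE) -> tuple[int, int]:
    """Byte range of a task: start = (task_id-1)*chunk_size, end = start+chunk_size-1.

    This mirrors the array-job arithmetic where the scheduler's 1-based task
    index selects which slice of the input file a worker aligns.
    """
    if task_id < 1:
        raise ValueError(f"task_id must be >= 1, got {task_id}")
    if chunk_size <= 0:
        raise ValueError(f"chunk_size must be positive, got {chunk_size}")
    start = (task_id - 1) * chunk_size
    return start, start + chunk_size - 1


def compute_chunk_plan(file_size: int, chunk_size: int = DEFAULT_CHUNK_SIZE) -> ChunkPlan:
    """Plan ceil(file_size / chunk_size) tasks covering the file.

    The final task's end offset is *not* clamped to the file size; readers
    simply stop at end-of-file. An empty file yields an empty plan.
    """
    if chunk_size <= 0:
        raise ValueError(f"chunk_size must be positive, got {chunk_size}")
    if file_size < 0:
        raise ValueError(f"file_size must be non-negative, got {file_size}")
    n = math.ceil(file_size / chunk_size)
    tasks = tuple(
        ChunkTask(i, *chunk_bounds(i, chunk_size)) for i in range(1, n + 1)
    )
    return ChunkPlan(file_size=file_size, chunk_size=chunk_size, tasks=tasks)


# ---------------------------------------------------------------------------
# Record-to-chunk assignment for text formats
# ---------------------------------------------------------------------------

def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".fastq", ".fq"):
        return "fastq"
    if suffix == ".sam":
        return "sam"
    raise ValueError(f"cannot infer record format from {path.name!r}; pass fmt=")


def assign_records_to_chunk(
    record_file: str | Path, start: int, end: int, fmt: str | None = None
) -> list[str]:
    """Return the records whose *first byte* lies within [start, end].

    A record belongs to the chunk containing its first byte; a chunk whose
    start lands mid-record scans forward to the next record boundary, so the
    union over all chunks of a plan is exactly the file's records, disjointly.
    Records are returned as their exact text (including newlines) so that
    concatenation across chunks is byte-identical to the record body of the
    file. SAM header lines are not records and are never returned.
    """
    path = Path(record_file)
    fmt = fmt or _sniff_format(path)
    with open(path, "rb") as fh:
        if fmt == "fastq":
            return _fastq_chunk_records(fh, path, start, end)
        if fmt == "sam":
            return _sam_chunk_records(fh, start, end)
    raise ValueError(f"unsupported record format {fmt!r}")


def _line_reader(fh, offset: int):
    """Yield (offset, line) pairs starting at the current file position."""
    while True:
        line = fh.readline()
        if not line:
            return
        yield offset, line
        offset += len(line)


def _seek_line_start(fh, start: int) -> int:
    """Seek to the first line start at or after byte `start`; return offset."""
    if start == 0:
        fh.seek(0)
        return 0
    fh.seek(start - 1)
    prev = fh.read(1)
    if prev == b"\n":
        return start
    # mid-line: the line owning byte `start` began earlier, skip its tail
    return start + len(fh.readline())


def _fastq_chunk_records(fh, path: Path, start: int, end: int) -> list[str]:
    offset = _seek_line_start(fh, start)
    lines = _line_reader(fh, offset)
    window: deque[tuple[int, bytes]] = deque()

    def fill(n: int) -> None:
        while len(window) < n:
            try:
                window.append(next(lines))
            except StopIteration:
                return

    # Locate the first record boundary: a line starting with '@' whose
    # second successor starts with '+'. A quality line may itself start with
    # '@', but is always followed by a header and then a sequence line, which
    # cannot start with '+', so the lookahead disambiguates.
    while True:
        fill(3)
        if not window or window[0][0] > end:
            return []
        l0 = window[0][1]
        if l0.startswith(b"@") and (len(window) < 3 or window[2][1].startswith(b"+")):
            break
        window.popleft()

    records: list[str] = []
    while window and window[0][0] <= end:
        fill(4)
        rec_off = window[0][0]
        if len(window) < 4:
            raise RecordBoundaryError(path, rec_off, "truncated FASTQ record")
        rec = [window.popleft() for _ in range(4)]
        if not rec[0][1].startswith(b"@") or not rec[2][1].startswith(b"+"):
            raise RecordBoundaryError(path, rec[0][0], "not a FASTQ record")
        records.append(b"".join(line for _, line in rec).decode())
        fill(1)
    return records


def _sam_chunk_records(fh, start: int, end: int) -> list[str]:
    offset = _seek_line_start(fh, start)
    records = []
    for off, line in _line_reader(fh, offset):
        if off > end:
            break
        if not line.startswith(b"@"):  # header lines are not records
            records.append(line.decode())
    return records


# ---------------------------------------------------------------------------
# Recursive concatenation
# ---------------------------------------------------------------------------

def _default_combine(group: Sequence[Any]) -> Any:
    first = group[0]
    if isinstance(first, bytes):
        return b"".join(group)
    if isinstance(first, str):
        return "".join(group)
    merged: list[Any] = []
    for part in group:
        merged.extend(part)
    return merged


def recursive_concat(
    parts: Sequence[Any],
    fan_in: int = DEFAULT_FAN_IN,
    combine: Callable[[Sequence[Any]], Any] | None = None,
) -> Any:
    """Merge parts in order, at most `fan_in` at a time, recursively.

    Bounding the fan-in bounds the number of simultaneously open part files,
    which is what lets concatenation scale to alignments of billions of
    reads without exhausting file descriptors. The result equals direct
    in-order concatenation for any fan_in >= 2.
    """
    if len(parts) == 0:
        raise ValueError("parts must be non-empty")
    if fan_in < 2:
        raise ValueError(f"fan_in must be >= 2, got {fan_in}")
    if combine is None:
        combine = _default_combine
    level = list(parts)
    if len(level) == 1:
        return level[0]
    while len(level) > 1:
        level = [combine(level[i : i + fan_in]) for i in range(0, len(level), fan_in)]
    return level[0]


# ---------------------------------------------------------------------------
# Status events and parallel execution
# ---------------------------------------------------------------------------

@dataclass
class StatusEvent:
    run_tag: str
    timestamp: float
    phase: str  # submitted | started | step | failed | completed
    message: str


class StatusLog:
    """Append-only event log for one run, optionally mirrored to JSON-lines."""

    def __init__(self, run_tag: str, path: str | Path | None = None):
        self.run_tag = run_tag
        self.path = Path(path) if path is not None else None
        self.events: list[StatusEvent] = []
        self._last = 0.0

    def emit(self, phase: str, message: str = "") -> StatusEvent:
        if phase not in STATUS_PHASES:
            raise ValueError(f"unknown status phase {phase!r}")
        ts = max(time.time(), self._last)  # monotone even under clock jitter
        self._last = ts
        event = StatusEvent(self.run_tag, ts, phase, message)
        self.events.append(event)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(asdict(event)) + "\n")
        return event

    @property
    def terminal_phase(self) -> str | None:
        for event in reversed(self.events):
            if event.phase in ("completed", "failed"):
                return event.phase
        return None


@dataclass
class TaskResult:
    task_id: int
    status: str  # completed | failed
    payload: Any = None
    diagnostics: str = ""


@dataclass
class PluginContract:
    """The four functions a grid-parallel plugin implements.

    `plan_split` and `count_chunks` default to byte-size planning when None.
    `combine` must be the identity on a singleton part list.
    """

    process_chunk: Callable[[Path, int, int], Any]
    combine: Callable[[list[Any]], Any]
    plan_split: Callable[[Path, int], ChunkPlan] | None = None
    count_chunks: Callable[[ChunkPlan], int] | None = None


@dataclass
class RunOutcome:
    result: Any
    task_results: list[TaskResult]
    log: StatusLog

    @property
    def events(self) -> list[StatusEvent]:
        return self.log.events

    @property
    def failed(self) -> bool:
        return self.log.terminal_phase == "failed"


def run_parallel(
    plugin: PluginContract,
    input_path: str | Path,
    *,
    workers: int = 2,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    tag: str = "LOCALRN",
    log_path: str | Path | None = None,
) -> RunOutcome:
    """Run a plugin over the chunks of a file and merge its part results.

    Every chunk yields exactly one TaskResult. Part results are combined in
    task-id order regardless of completion order, so output is deterministic.
    Combination proceeds even if some tasks failed, producing a result that
    covers exactly the completed chunks; the run is marked failed only when
    no chunk could be processed at all.
    """
    path = Path(input_path)
    log = StatusLog(tag, log_path)
    if not path.is_file() or not os.access(path, os.R_OK):
        raise OSError(f"input not readable: {path}")
    if plugin.plan_split is not None:
        plan = plugin.plan_split(path, chunk_size)
    else:
        plan = compute_chunk_plan(path.stat().st_size, chunk_size)
    n = plugin.count_chunks(plan) if plugin.count_chunks is not None else plan.n_tasks
    log.emit("submitted", f"{n} tasks, chunk_size={plan.chunk_size}")
    log.emit("started", str(path))

    task_results: list[TaskResult] = []
    with ThreadPoolExecutor(max_workers=max(1, workers)) as pool:
        futures = {
            task.task_id: pool.submit(plugin.process_chunk, path, task.start, task.end)
            for task in plan.tasks
        }
        for task in plan.tasks:
            try:
                payload = futures[task.task_id].result()
            except Exception as exc:  # a failed chunk must not sink the run
                tr = TaskResult(task.task_id, "failed", None, f"{type(exc).__name__}: {exc}")
                log.emit("step", f"task {task.task_id}/{n} failed: {exc}")
            else:
                tr = TaskResult(task.task_id, "completed", payload)
                log.emit("step", f"task {task.task_id}/{n} completed")
            task_results.append(tr)

    parts = [tr.payload for tr in task_results if tr.status == "completed"]
    if plan.n_tasks > 0 and not parts:
        log.emit("failed", "all chunks failed")
        return RunOutcome(None, task_results, log)
    result = plugin.combine(parts)
    n_failed = sum(tr.status == "failed" for tr in task_results)
    suffix = f", {n_failed} failed" if n_failed else ""
    log.emit("completed", f"{len(parts)}/{plan.n_tasks} chunks combined{suffix}")
    return RunOutcome(result, task_results, log)
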