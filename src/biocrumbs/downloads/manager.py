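"""Tracked, admission-controlled downloads of GEO SOFT archives.

Transfers run on worker threads behind a semaphore (bounded concurrency,
three by default). Admission — per-file limit, total-storage budget from an
on-disk scan, free-space check — happens before any byte is written, and a
transfer whose server advertises no length is aborted the moment it exceeds
the per-file limit. Each completed job leaves ``family.soft.gz`` plus a
``metadata.xml`` built from the accession's ESummary record.
"""

from __future__ import annotations

import shutil
import threading
import time
import urllib.error
import urllib.request
import uuid
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from ..errors import NotFoundError
from ..eutils.client import EsummaryRecord
from .policy import DownloadPolicy, admit_job, validate_path

_CHUNK = 64 * 1024

# {accession} and {series_stub} are filled per accession; series_stub is the
# accession with its trailing three digits replaced by "nnn" (GEO FTP layout).
DEFAULT_URL_TEMPLATE = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/{series_stub}/{accession}/soft/"
    "{accession}_family.soft.gz"
)

_VALID_PREFIXES = ("GSE", "GSM", "GPL", "GDS")


@dataclass
class DownloadJob:
    """One tracked transfer with a monotone state machine.

    States move along queued→running→{completed|failed} or queued→rejected;
    ``bytes_done`` never decreases.
    """

    job_id: str
    accession: str
    archive_path: Path
    metadata_path: Path
    state: str = "queued"
    bytes_done: int = 0
    error: Optional[str] = None
    created: float = field(default_factory=time.time)
    started: Optional[float] = None
    finished: Optional[float] = None

    def snapshot(self) -> dict:
        return {
            "job_id": self.job_id,
            "accession": self.accession,
            "state": self.state,
            "bytes_done": self.bytes_done,
            "error": self.error,
            "archive_path": str(self.archive_path),
            "metadata_path": str(self.metadata_path),
            "created": self.created,
            "started": self.started,
            "finished": self.finished,
        }


def series_stub(accession: str) -> str:
    head = accession[:-3] if len(accession) > 3 + 3 else accession[:3]
    return head + "nnn"


def metadata_xml(record: EsummaryRecord | None, accession: str) -> bytes:
    """Render the ESummary record (or a minimal stub) as metadata XML."""
    root = ET.Element("geo_metadata", attrib={"accession": accession})
    if record is not None:
        for tag, value in (
            ("uid", record.uid),
            ("accession", record.accession),
            ("title", record.title),
            ("summary", record.summary),
            ("organism", record.organism or ""),
            ("entry_type", record.entry_type or ""),
        ):
            ET.SubElement(root, tag).text = value
    return ET.tostring(root, encoding="utf-8", xml_declaration=True)


class DownloadManager:
    """Admission, execution and status tracking for SOFT downloads."""

    def __init__(
        self,
        policy: DownloadPolicy,
        url_template: str = DEFAULT_URL_TEMPLATE,
        metadata_provider: Callable[[str], EsummaryRecord | None] | None = None,
        synchronous: bool = False,
    ):
        self.policy = policy
        self.url_template = url_template
        self.metadata_provider = metadata_provider or (lambda accession: None)
        self.synchronous = synchronous
        self._jobs: dict[str, DownloadJob] = {}
        self._lock = threading.Lock()
        self._semaphore = threading.Semaphore(policy.max_concurrent)
        self._threads: list[threading.Thread] = []
        Path(policy.root_dir).mkdir(parents=True, exist_ok=True)

    # -- public surface -------------------------------------------------

    def download_geo_data(self, accession: str) -> DownloadJob:
        """Admit and enqueue one accession; returns the tracked job."""
        accession = str(accession).strip().upper()
        if accession[:3] not in _VALID_PREFIXES or not accession[3:].isdigit():
            raise NotFoundError(f"not a recognized GEO accession: {accession!r}")
        archive = validate_path(self.policy.root_dir, f"{accession}/family.soft.gz")
        metadata = validate_path(self.policy.root_dir, f"{accession}/metadata.xml")
        job = DownloadJob(
            job_id=uuid.uuid4().hex[:12],
            accession=accession,
            archive_path=archive,
            metadata_path=metadata,
        )
        with self._lock:
            self._jobs[job.job_id] = job

        url = self.url_template.format(
            accession=accession, series_stub=series_stub(accession)
        )
        admitted, reason = self._admit(url, job)
        if not admitted:
            job.state = "rejected"
            job.error = f"admission rejected: {reason}"
            job.finished = time.time()
            return job
        if self.synchronous:
            self._run(job, url)
        else:
            thread = threading.Thread(target=self._run, args=(job, url), daemon=True)
            self._threads.append(thread)
            thread.start()
        return job

    def get_download_status(self, job_id: str | None = None) -> list[dict]:
        """Snapshot one job (or all); unknown ids yield a not-found record."""
        with self._lock:
            if job_id is None:
                return [job.snapshot() for job in self._jobs.values()]
            job = self._jobs.get(str(job_id))
        if job is None:
            return [{"job_id": str(job_id), "state": "not_found",
                     "error": f"unknown job id: {job_id}"}]
        return [job.snapshot()]

    def wait_all(self, timeout: float = 60.0) -> None:
        deadline = time.monotonic() + timeout
        for thread in self._threads:
            thread.join(max(0.0, deadline - time.monotonic()))

    def jobs(self) -> list[DownloadJob]:
        with self._lock:
            return list(self._jobs.values())

    # -- internals ------------------------------------------------------

    def _disk_usage(self) -> int:
        root = Path(self.policy.root_dir)
        return sum(p.stat().st_size for p in root.rglob("*") if p.is_file())

    def _advertised_size(self, url: str) -> int | None:
        try:
            req = urllib.request.Request(url, method="HEAD")
            with urllib.request.urlopen(req, timeout=self.policy.request_timeout) as resp:
                length = resp.headers.get("Content-Length")
                return int(length) if length is not None else None
        except (urllib.error.URLError, ValueError, TimeoutError, OSError):
            return None  # unknown size: admitted conservatively, capped mid-transfer

    def _admit(self, url: str, job: DownloadJob) -> tuple[bool, str | None]:
        advertised = self._advertised_size(url)
        usage = self._disk_usage()
        free = shutil.disk_usage(self.policy.root_dir).free
        return admit_job(self.policy, advertised or 0, usage, free)

    def _run(self, job: DownloadJob, url: str) -> None:
        with self._semaphore:
            job.state = "running"
            job.started = time.time()
            try:
                self._transfer(job, url)
                self._write_metadata(job)
                job.state = "completed"
            except Exception as exc:
                job.state = "failed"
                job.error = f"{type(exc).__name__}: {exc}"
                for path in (job.archive_path, job.metadata_path):
                    path.unlink(missing_ok=True)
            finally:
                job.finished = time.time()

    def _transfer(self, job: DownloadJob, url: str) -> None:
        job.archive_path.parent.mkdir(parents=True, exist_ok=True)
        tmp = job.archive_path.with_suffix(job.archive_path.suffix + ".part")
        try:
            with urllib.request.urlopen(url, timeout=self.policy.request_timeout) as resp:
                with open(tmp, "wb") as out:
                    while True:
                        chunk = resp.read(_CHUNK)
                        if not chunk:
                            break
                        out.write(chunk)
                        job.bytes_done += len(chunk)
                        if job.bytes_done > self.policy.per_file_limit:
                            raise RuntimeError(
                                f"transfer exceeded per-file limit "
                                f"({self.policy.per_file_limit} bytes); aborted"
                            )
            tmp.replace(job.archive_path)
        finally:
            tmp.unlink(missing_ok=True)

    def _write_metadata(self, job: DownloadJob) -> None:
        record = None
        try:
            record = self.metadata_provider(job.accession)
        except Exception:
            record = None  # metadata is best-effort; the archive is the artifact
        job.metadata_path.write_bytes(metadata_xml(record, job.accession))
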