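"""Safety controls: path confinement, admission, transfers, status tracking."""

import gzip
import os
import random
import string
import time

import pytest
from hypothesis import given, settings, strategies as st

from biocrumbs.downloads.manager import DownloadManager, series_stub
from biocrumbs.downloads.policy import DownloadPolicy, admit_job, validate_path
from biocrumbs.errors import NotFoundError, PathError
from biocrumbs.mock.files import FileCatalogEntry, MockFileServer

GIB = 1024**3


class TestValidatePath:
    def test_in_root_composition_accepted(self, tmp_path):
        path = validate_path(tmp_path, "GSE271535/family.soft.gz")
        assert str(path).startswith(str(tmp_path))

    @pytest.mark.parametrize(
        "candidate",
        ["../../etc/passwd", "..", "a/../../b", "/etc/passwd", "a/b/../../../c"],
    )
    def test_escape_attempts_rejected(self, tmp_path, candidate):
        with pytest.raises(PathError):
            validate_path(tmp_path, candidate)

    def test_internal_dotdot_that_stays_inside_accepted(self, tmp_path):
        path = validate_path(tmp_path, "a/b/../c")
        assert path == tmp_path / "a" / "c"

    def test_fuzz_against_canonicalization_oracle(self, tmp_path):
        """1000 random segment paths: accepted iff the brute-force canonical
        form (os.path.normpath on the joined path) stays under the root."""
        rng = random.Random(7)
        segments = ["..", ".", "data", "GSE1", "x", "deep/../up"]
        root = os.path.normpath(str(tmp_path))
        for _ in range(1000):
            candidate = "/".join(
                rng.choice(segments) for _ in range(rng.randint(1, 6))
            )
            expected_ok = (
                os.path.normpath(os.path.join(root, candidate)) == root
                or os.path.normpath(os.path.join(root, candidate)).startswith(root + os.sep)
            )
            try:
                validate_path(tmp_path, candidate)
                actual_ok = True
            except PathError:
                actual_ok = False
            assert actual_ok == expected_ok, candidate


class TestAdmitJob:
    def policy(self, tmp_path):
        return DownloadPolicy(root_dir=tmp_path, free_space_margin=100)

    def test_per_file_limit_plus_one_rejected(self, tmp_path):
        policy = self.policy(tmp_path)
        admitted, reason = admit_job(policy, policy.per_file_limit + 1, 0, 100 * GIB)
        assert (admitted, reason) == (False, "per_file")

    def test_total_budget_exhausted_rejected(self, tmp_path):
        policy = self.policy(tmp_path)
        admitted, reason = admit_job(policy, 2 * GIB, 9 * GIB, 100 * GIB)
        assert (admitted, reason) == (False, "total")

    def test_insufficient_free_space_rejected(self, tmp_path):
        policy = self.policy(tmp_path)
        admitted, reason = admit_job(policy, GIB, 0, GIB // 2)
        assert (admitted, reason) == (False, "disk")

    def test_zero_size_ample_space_admitted(self, tmp_path):
        assert admit_job(self.policy(tmp_path), 0, 0, 10 * GIB) == (True, None)

    def test_printed_default_limits(self, tmp_path):
        policy = DownloadPolicy(root_dir=tmp_path)
        assert policy.per_file_limit == 5 * GIB
        assert policy.total_limit == 10 * GIB
        assert policy.max_concurrent == 3
        assert policy.request_timeout == 300.0

    @settings(max_examples=150, deadline=None)
    @given(
        size=st.integers(min_value=0, max_value=12 * GIB),
        usage=st.integers(min_value=0, max_value=12 * GIB),
        free=st.integers(min_value=0, max_value=12 * GIB),
    )
    def test_randomized_triples_match_brute_force(self, size, usage, free, tmp_path_factory):
        """Decision equals re-evaluating the three inequalities in order."""
        policy = DownloadPolicy(
            root_dir=tmp_path_factory.getbasetemp(), free_space_margin=100 * 1024**2
        )
        if size > policy.per_file_limit:
            expected = (False, "per_file")
        elif usage + size > policy.total_limit:
            expected = (False, "total")
        elif free < size + policy.free_space_margin:
            expected = (False, "disk")
        else:
            expected = (True, None)
        assert admit_job(policy, size, usage, free) == expected


def _soft_payload() -> bytes:
    lines = [
        "^SERIES = GSE278158",
        "!Series_title = SRC-1 in aging-associated cognitive decline",
        "!Series_sample_id = GSM1001",
        "^SAMPLE = GSM1001",
        "!Sample_title = hippocampus rep1",
        "#ID_REF = probe identifier",
        "#VALUE = normalized signal",
        "!sample_table_begin",
        "probe1\t10.2",
        "probe2\t8.4",
        "!sample_table_end",
    ]
    return gzip.compress(("\n".join(lines) + "\n").encode())


@pytest.fixture()
def file_server():
    catalog = {
        "geo/series/GSE278nnn/GSE278158/soft/GSE278158_family.soft.gz": FileCatalogEntry(
            payload=_soft_payload()
        ),
        "huge.soft.gz": FileCatalogEntry(payload=b"tiny", advertised_size=6 * GIB),
    }
    # five slow files for the concurrency probe
    for i in range(5):
        catalog[f"geo/series/GSE10nnn/GSE1000{i}/soft/GSE1000{i}_family.soft.gz"] = (
            FileCatalogEntry(payload=b"x" * 4096, delay_per_chunk=0.08, chunk_size=512)
        )
    with MockFileServer(catalog) as server:
        yield server


def make_manager(tmp_path, server, **overrides) -> DownloadManager:
    policy = DownloadPolicy(
        root_dir=tmp_path / "downloads",
        free_space_margin=1,
        request_timeout=overrides.pop("request_timeout", 10.0),
        **overrides,
    )
    return DownloadManager(
        policy,
        url_template=server.base_url
        + "/geo/series/{series_stub}/{accession}/soft/{accession}_family.soft.gz",
    )


class TestDownloadManager:
    def test_series_stub_layout(self):
        assert series_stub("GSE278158") == "GSE278nnn"
        assert series_stub("GSE1") == "GSEnnn"

    def test_small_archive_completes_with_both_files(self, tmp_path, file_server):
        manager = make_manager(tmp_path, file_server)
        manager.synchronous = True
        job = manager.download_geo_data("GSE278158")
        assert job.state == "completed"
        assert job.archive_path.exists()
        assert job.metadata_path.exists()
        assert job.bytes_done == job.archive_path.stat().st_size
        assert b"GSE278158" in job.metadata_path.read_bytes()

    def test_unrecognized_accession_rejected_upfront(self, tmp_path, file_server):
        manager = make_manager(tmp_path, file_server)
        with pytest.raises(NotFoundError):
            manager.download_geo_data("SRR123")

    def test_oversized_advertised_length_rejected_nothing_written(self, tmp_path):
        catalog = {"path/GSE99999_family.soft.gz": FileCatalogEntry(
            payload=b"tiny", advertised_size=6 * GIB)}
        with MockFileServer(catalog) as server:
            manager = DownloadManager(
                DownloadPolicy(root_dir=tmp_path / "dl", free_space_margin=1),
                url_template=server.base_url + "/path/{accession}_family.soft.gz",
                synchronous=True,
            )
            job = manager.download_geo_data("GSE99999")
        assert job.state == "rejected"
        assert "per_file" in job.error
        assert job.bytes_done == 0
        assert list((tmp_path / "dl").rglob("*.gz")) == []

    def test_unknown_length_stream_aborted_at_per_file_limit(self, tmp_path):
        catalog = {"path/GSE88888_family.soft.gz": FileCatalogEntry(
            payload=b"y" * 8192, advertised_size=None, chunk_size=256)}
        with MockFileServer(catalog) as server:
            manager = DownloadManager(
                DownloadPolicy(
                    root_dir=tmp_path / "dl", per_file_limit=2048, free_space_margin=1
                ),
                url_template=server.base_url + "/path/{accession}_family.soft.gz",
                synchronous=True,
            )
            job = manager.download_geo_data("GSE88888")
        assert job.state == "failed"
        assert "per-file limit" in job.error
        assert not job.archive_path.exists()  # partial file cleaned up

    def test_concurrency_bound_is_max_concurrent(self, tmp_path, file_server):
        manager = make_manager(tmp_path, file_server)
        jobs = [manager.download_geo_data(f"GSE1000{i}") for i in range(5)]
        manager.wait_all(timeout=30)
        assert all(j.state == "completed" for j in jobs)
        assert file_server.max_active == manager.policy.max_concurrent == 3

    def test_status_snapshots(self, tmp_path, file_server):
        manager = make_manager(tmp_path, file_server)
        manager.synchronous = True
        job = manager.download_geo_data("GSE278158")
        (status,) = manager.get_download_status(job.job_id)
        assert status["state"] == "completed"
        assert status["bytes_done"] == job.archive_path.stat().st_size
        (missing,) = manager.get_download_status("nope")
        assert missing["state"] == "not_found"
        assert len(manager.get_download_status()) == 1

    def test_usage_accounting_respects_total_limit(self, tmp_path, file_server):
        """Second job is rejected when the first already fills the budget."""
        manager = make_manager(tmp_path, file_server, total_limit=400)
        manager.synchronous = True
        first = manager.download_geo_data("GSE278158")
        assert first.state == "completed"
        second = manager.download_geo_data("GSE278158")
        assert second.state == "rejected"
        assert "total" in second.error
        usage = sum(
            p.stat().st_size for p in manager.policy.root_dir.rglob("*") if p.is_file()
        )
        assert usage <= manager.policy.total_limit
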