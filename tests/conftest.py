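import pytest

from surglearn.cohort import CaseRecord, ComplicationEvent


@pytest.fixture
def small_cohort() -> list[CaseRecord]:
    """Three-case cohort with one missing CSS cell and one complication."""
    return [
        CaseRecord(1, {"oss": 30.0, "css": 40.0, "flexion": 90.0}),
        CaseRecord(
            2,
            {"oss": 35.0, "css": None, "flexion": 100.0},
            [ComplicationEvent("nerve palsy", "minor", 0.0, True, "full recovery")],
        ),
        CaseRecord(3, {"oss": 40.0, "css": 55.0, "flexion": 110.0}),
    ]


@pytest.fixture
def cohort_csv(tmp_path):
    """Factory writing a cohort CSV from rows of column->value dicts."""

    def write(rows, name="cohort.csv"):
        columns: list[str] = []
        for row in rows:
            for key in row:
                if key not in columns:
                    columns.append(key)
        lines = [",".join(columns)]
        for row in rows:
            lines.append(
                ",".join("" if row.get(c) is None else str(row.get(c, "")) for c in columns)
            )
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return write
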