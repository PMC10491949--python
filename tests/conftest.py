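from __future__ import annotations

from pathlib import Path

import pytest

from metlink import FixtureSpec, write_fixtures

# Hand-written catalog: 12 data rows, 1 malformed (no PubMed id), and
# 5 distinct (pubmed, study, trait) triples among the retained rows.
HAND_CATALOG = "\t".join(["PUBMEDID", "STUDY", "DISEASE/TRAIT", "SNPS", "MAPPED_GENE"]) + "\n" + "\n".join(
    [
        "101\tPlasma lipidome study\tChronic kidney disease\trs1\tAPOA5 - APOC3",
        "101\tPlasma lipidome study\tChronic kidney disease\trs2\tNR",
        "101\tPlasma lipidome study\tChronic kidney disease\trs3\tagxt2, Clybl ",
        "101\tPlasma lipidome study\tSerum urate levels\trs4\tSLC2A9",
        "101\tPlasma lipidome study\tSerum urate levels\trs5\tABCG2; PDZK1",
        "202\tUrine metabolome scan\tUrinary metabolite ratios\trs6\tAGXT2",
        "202\tUrine metabolome scan\tUrinary metabolite ratios\trs7\tHLA-B",
        "303\tHeart failure consortium\tCardiovascular disease\trs8\tPLA2G7",
        "303\tHeart failure consortium\tCardiovascular disease\trs9\tAPOA5",
        "404\tGlycaemic traits meta-analysis\tFasting glucose\trs10\tGCK",
        "404\tGlycaemic traits meta-analysis\tFasting glucose\trs11\t",
        "\tOrphan row without identifier\tUnknown trait\trs12\tBAD1",
    ]
) + "\n"


@pytest.fixture
def hand_catalog_path(tmp_path: Path) -> Path:
    path = tmp_path / "hand_catalog.tsv"
    path.write_text(HAND_CATALOG, encoding="utf-8")
    return path


@pytest.fixture
def fixture_spec() -> FixtureSpec:
    return FixtureSpec(seed=11)


@pytest.fixture
def fixture_dir(tmp_path: Path, fixture_spec: FixtureSpec) -> dict[str, Path]:
    return write_fixtures(fixture_spec, tmp_path / "fixtures")
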