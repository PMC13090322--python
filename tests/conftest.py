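import io

import pytest

from zincredox.proteome_io import parse_proteome_table

HEADER = (
    "accession\tentry_name\tgene_name\tsequence\treviewed\tfragment\tec_number\t"
    "go_mf\tcofactor\tbinding_site\tzinc_finger\tkeywords\tpdb_ids"
)


def make_row(accession, sequence, gene="", reviewed="yes", fragment="no", ec="",
             go="", cofactor="", binding="", finger="", keywords="", pdb=""):
    return "\t".join([accession, f"{accession}_X", gene, sequence, reviewed,
                      fragment, ec, go, cofactor, binding, finger, keywords, pdb])


def make_table(rows):
    return HEADER + "\n" + "\n".join(rows) + "\n"


@pytest.fixture
def small_proteome():
    rows = [
        make_row("P00001", "MCAACDEFGHIKLMNP", gene="GEN1",
                 go="zinc ion binding", binding="2:Zn(2+);5:Zn(2+)"),
        make_row("P00002", "MADEFGHIKLMNPQRS", gene="GEN2", keywords="Metal-binding"),
        make_row("P00003", "MCAAACDEFGHIKLMN", gene="GEN3"),
    ]
    return parse_proteome_table(io.StringIO(make_table(rows)))
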