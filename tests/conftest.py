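import numpy as np
import pytest

# Worked-example chain: the 20-residue Trp-cage miniprotein in its fully
# extended conformation (N segments, contour length in A).
TRP_N = 20
TRP_L = 73.61
TRP_A = TRP_L / TRP_N


@pytest.fixture
def rng():
    return np.random.default_rng(20220160)


@pytest.fixture
def two_model_pdb(tmp_path):
    """Minimal 2-MODEL PDB with 3 CA atoms each plus decoy N/altloc atoms."""
    def atom(serial, name, resname, resseq, x, y, z, altloc=" "):
        return (f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:3s} A{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")

    lines = ["MODEL        1",
             atom(1, " N  ", "ALA", 1, 0.0, 0.0, 0.0),
             atom(2, " CA ", "ALA", 1, 1.0, 0.0, 0.0),
             atom(3, " CA ", "GLY", 2, 2.0, 0.0, 0.0, altloc="A"),
             atom(4, " CA ", "GLY", 2, 9.0, 9.0, 9.0, altloc="B"),
             atom(5, " CA ", "SER", 3, 3.0, 0.0, 0.0),
             "ENDMDL",
             "MODEL        2",
             atom(6, " N  ", "ALA", 1, 0.0, 1.0, 0.0),
             atom(7, " CA ", "ALA", 1, 1.0, 1.0, 0.0),
             atom(8, " CA ", "GLY", 2, 2.0, 1.0, 0.0, altloc="A"),
             atom(9, " CA ", "SER", 3, 3.0, 1.0, 0.0),
             "ENDMDL",
             "END"]
    path = tmp_path / "two_model.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
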