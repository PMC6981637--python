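import numpy as np
import pytest

from cholinib.pose_io import CoreAtomMap, LigandPose
from cholinib.registry import load_registry
from cholinib.synthetic import PoseEnsembleConfig, gen_pose_ensemble


@pytest.fixture(scope="session")
def registry_records():
    return load_registry()


@pytest.fixture(scope="session")
def registry_by_id(registry_records):
    return {r.id: r for r in registry_records}


@pytest.fixture(scope="session")
def small_ensemble():
    """Compact two-mode ensemble: 6 ligands, 20 poses each, well separated."""
    cfg = PoseEnsembleConfig(n_ligands=6, poses_per_ligand=20, seed=11)
    poses, table, truth, core_map = gen_pose_ensemble(cfg)
    return poses, table, truth, core_map


def make_pose(names, coords, ligand="ligA", stereo="R", receptor="rec00", index=0,
              docking=-5.0, rescore=None, elements=None):
    return LigandPose(
        ligand_id=ligand,
        stereo_tag=stereo,
        receptor_id=receptor,
        pose_index=index,
        atom_names=list(names),
        elements=elements or ["C"] * len(names),
        coords=np.asarray(coords, dtype=float),
        docking_score=docking,
        rescore_dg=rescore,
    )


@pytest.fixture
def tiny_map():
    return CoreAtomMap(("A1", "A2", "A3", "A4", "A5"))
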