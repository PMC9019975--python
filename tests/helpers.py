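import numpy as np
import scipy.sparse as sp

from metapile.data_io import UMIMatrix


def dense_matrix(array, cell_prefix="c", gene_prefix="g") -> UMIMatrix:
    """UMIMatrix from a dense list/array, with generated axis names."""
    array = np.asarray(array)
    cells = np.array([f"{cell_prefix}{i}" for i in range(array.shape[0])], dtype=object)
    genes = np.array([f"{gene_prefix}{j}" for j in range(array.shape[1])], dtype=object)
    return UMIMatrix(sp.csr_matrix(array), cells, genes)
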