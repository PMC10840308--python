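# Synthetic light-atom Slater wavefunction table.
# Hydrogen: exact single-zeta STO with the bonded-atom exponent 1.15 bohr^-1.
# All other entries: synthetic minimal-basis single-zeta wavefunctions from
# Slater's screening rules, generated by slaterff.fixtures.slater_rules_wavefunction.
# They stand in for large-basis Hartree-Fock Slater tables, which are not bundled;
# the file format accepts transcriptions of those tables unchanged.

# exact single-zeta hydrogen, zeta=1.15
ELEMENT H 1 0
ORBITAL 1s 0 1
PRIM 1 1.15 1

# synthetic minimal-basis wavefunction (Slater screening rules)
ELEMENT C 6 0
ORBITAL 1s 0 2
PRIM 1 5.7 1
ORBITAL 2s 0 2
PRIM 2 1.8 1
ORBITAL 2p 1 2
PRIM 2 1.8 1

# synthetic minimal-basis wavefunction (Slater screening rules)
ELEMENT N 7 0
ORBITAL 1s 0 2
PRIM 1 6.7 1
ORBITAL 2s 0 2
PRIM 2 2.125 1
ORBITAL 2p 1 3
PRIM 2 2.125 1

# synthetic minimal-basis wavefunction (Slater screening rules)
ELEMENT O 8 -1
ORBITAL 1s 0 2
PRIM 1 7.7 1
ORBITAL 2s 0 2
PRIM 2 2.275 1
ORBITAL 2p 1 5
PRIM 2 2.275 1

# synthetic minimal-basis wavefunction (Slater screening rules)
ELEMENT O 8 0
ORBITAL 1s 0 2
PRIM 1 7.7 1
ORBITAL 2s 0 2
PRIM 2 2.45 1
ORBITAL 2p 1 4
PRIM 2 2.45 1

# synthetic minimal-basis wavefunction (Slater screening rules)
ELEMENT Na 11 0
ORBITAL 1s 0 2
PRIM 1 10.7 1
ORBITAL 2s 0 2
PRIM 2 3.6 1
ORBITAL 2p 1 6
PRIM 2 3.6 1
ORBITAL 3s 0 1
PRIM 3 0.7333333333 1

# synthetic minimal-basis wavefunction (Slater screening rules)
ELEMENT Na 11 1
ORBITAL 1s 0 2
PRIM 1 10.7 1
ORBITAL 2s 0 2
PRIM 2 3.6 1
ORBITAL 2p 1 6
PRIM 2 3.6 1

# synthetic minimal-basis wavefunction (Slater screening rules)
ELEMENT Cl 17 -1
ORBITAL 1s 0 2
PRIM 1 16.7 1
ORBITAL 2s 0 2
PRIM 2 6.6 1
ORBITAL 2p 1 6
PRIM 2 6.6 1
ORBITAL 3s 0 2
PRIM 3 2.033333333 1
ORBITAL 3p 1 6
PRIM 3 2.033333333 1

# synthetic minimal-basis wavefunction (Slater screening rules)
ELEMENT Cl 17 0
ORBITAL 1s 0 2
PRIM 1 16.7 1
ORBITAL 2s 0 2
PRIM 2 6.6 1
ORBITAL 2p 1 6
PRIM 2 6.6 1
ORBITAL 3s 0 2
PRIM 3 2.15 1
ORBITAL 3p 1 5
PRIM 3 2.15 1

# synthetic minimal-basis wavefunction (Slater screening rules)
ELEMENT Ca 20 0
ORBITAL 1s 0 2
PRIM 1 19.7 1
ORBITAL 2s 0 2
PRIM 2 8.1 1
ORBITAL 2p 1 6
PRIM 2 8.1 1
ORBITAL 3s 0 2
PRIM 3 3.033333333 1
ORBITAL 3p 1 6
PRIM 3 3.033333333 1
ORBITAL 4s 0 2
PRIM 4 0.7702702703 1

# synthetic minimal-basis wavefunction (Slater screening rules)
ELEMENT Ca 20 1
ORBITAL 1s 0 2
PRIM 1 19.7 1
ORBITAL 2s 0 2
PRIM 2 8.1 1
ORBITAL 2p 1 6
PRIM 2 8.1 1
ORBITAL 3s 0 2
PRIM 3 3.033333333 1
ORBITAL 3p 1 6
PRIM 3 3.033333333 1
ORBITAL 4s 0 1
PRIM 4 0.8648648649 1
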