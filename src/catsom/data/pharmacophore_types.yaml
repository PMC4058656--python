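# Pharmacophore atom-typing rules for the CATS descriptor.
#
# Five potential-pharmacophore-point types: D (hydrogen-bond donor),
# A (hydrogen-bond acceptor), P (positively ionizable), N (negatively
# ionizable), L (lipophilic).  An atom may carry several types.
#
# These rules are frozen: changing them changes every descriptor value and
# is therefore a breaking change.  Bump `version` on any edit.
version: 1
donor:
  # O or N bearing at least one hydrogen
  - "[#7;!H0]"
  - "[#8;!H0]"
acceptor:
  # any oxygen except nitro-group oxygens
  - "[#8;!$([#8]~[#7]~[#8X1])]"
  # nitrogen that is neither positively charged, nor pyrrole-type aromatic
  # (lone pair in the ring), nor an amide nitrogen
  - "[#7;+0;!$([nX3]);!$([NX3][CX3]=[OX1])]"
positive:
  # any positively charged atom
  - "[*;+]"
  # aliphatic amine N (primary/secondary/tertiary; not amide, not aniline,
  # not enamine)
  - "[NX3;+0;!$([NX3][CX3]=[OX1,SX1,NX2]);!$([NX3][a]);!$([NX3][CX3]=[CX3])]"
  # amidine / guanidine central carbon
  - "[CX3](=[NX2])[NX3]"
negative:
  # any negatively charged atom
  - "[*;-]"
  # carboxylic acid carbon
  - "[CX3](=[OX1])[OX2H1]"
  # sulfonic acid sulfur
  - "[SX4](=[OX1])(=[OX1])[OX2H1]"
  # phosphonic acid phosphorus
  - "[PX4](=[OX1])([OX2H1])"
  # acylsulfonamide nitrogen
  - "[NX3H1]([CX3]=[OX1])[SX4](=[OX1])=[OX1]"
  # tetrazole carbon (N-H tautomer)
  - "[c]1[n][n][n][nH]1"
lipophilic:
  # C, S or Cl whose heavy-atom neighbours are exclusively C or S
  # (hydrogens always allowed); evaluated programmatically, recorded here
  # for documentation and versioning
  elements: [C, S, Cl]
  allowed_neighbors: [C, S]
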