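# CYP2A6 star-allele definitions over the 14-SNP panel (synthetic
# reconstruction of the published function grouping; the full published
# SNP->allele circle mapping is not printed anywhere, so this config is a
# best-effort one-SNP-per-allele assignment and is meant to be edited).
#
# Anchors that are pinned by the residue change in the PharmVar catalogue:
#   *2  = rs1801272  (L160H)        *5  = rs5031017   (G479V)
#   *7  = rs5031016  (I471T)        *9  = rs28399433  (TATA-box -48T>G)
#   *13 = rs28399434 (G5R)          *15 = rs199916117 (K194E)
#   *21 = rs6413474  (K476R)
# The remaining assignments are panel-internal placeholders chosen so that
# every panel SNP discriminates exactly one allele.  Function classes
# follow the published grouping: loss-of-function {*2,*5,*10}, decreased
# {*7,*9,*13,*15,*19,*21,*38}, normal {*1,*8}, unknown {*18,*36,*37}.
# Required alleles are on the canonical panel strand.
alleles:
  "*1":
    function: normal
    snps: {}
  "*2":
    function: loss_of_function
    snps: {rs1801272: T}
  "*5":
    function: loss_of_function
    snps: {rs5031017: A}
  "*7":
    function: decreased
    snps: {rs5031016: G}
  "*8":
    function: normal
    snps: {rs28399468: A}
  "*9":
    function: decreased
    snps: {rs28399433: C}
  "*10":
    function: loss_of_function
    snps: {rs2431413: G}
  "*13":
    function: decreased
    snps: {rs28399434: T}
  "*15":
    function: decreased
    snps: {rs199916117: C}
  "*18":
    function: unknown
    snps: {rs1809810: A}
  "*19":
    function: decreased
    snps: {rs148166815: G}
  "*21":
    function: decreased
    snps: {rs6413474: C}
  "*36":
    function: unknown
    snps: {rs8192720: A}
  # rs1137115's change notation is reversed (the catalogued minor allele is
  # the first letter); the variant allele on the panel strand is T
  "*37":
    function: unknown
    snps: {rs1137115: T}
  "*38":
    function: decreased
    snps: {rs143731390: A}
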