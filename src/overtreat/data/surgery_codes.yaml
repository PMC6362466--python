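# Default surgery code map: registry procedure label -> analysis class.
#
# Total mastectomy means simple mastectomy or modified radical mastectomy.
# Breast-conserving surgery (bcs) covers lumpectomy and the related partial
# resections.  Other surgical therapies (including subcutaneous mastectomy
# and the historical radical procedures) are classed "other"; "none" means
# no surgery of the primary site.  Keys are matched case-insensitively;
# registries using numeric site-specific codes should supply their own map.
simple mastectomy: mastectomy
total mastectomy: mastectomy
modified radical mastectomy: mastectomy
lumpectomy: bcs
excisional biopsy: bcs
segmental mastectomy: bcs
subtotal mastectomy: bcs
quadrantectomy: bcs
tylectomy: bcs
wedge resection: bcs
nipple resection: bcs
partial mastectomy nos: bcs
subcutaneous mastectomy: other
radical mastectomy: other
extended radical mastectomy: other
mastectomy nos: other
surgery nos: other
no surgery: none
none: none
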