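endpoint_group,code_prefix,label
breast,8542,Bilateral simple mastectomy
breast,8544,Bilateral extended simple mastectomy
breast,8546,Bilateral radical mastectomy
breast,8548,Bilateral extended radical mastectomy
uterus,683,Subtotal abdominal hysterectomy
uterus,684,Total abdominal hysterectomy
uterus,685,Vaginal hysterectomy
uterus,686,Radical abdominal hysterectomy
uterus,687,Radical vaginal hysterectomy
uterus,689,Other and unspecified hysterectomy
ovary,6551,Bilateral oophorectomy
ovary,6553,Bilateral oophorectomy remaining ovary
ovary,6561,Bilateral salpingo-oophorectomy
ovary,6563,Bilateral salpingo-oophorectomy remaining adnexa
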