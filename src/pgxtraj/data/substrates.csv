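atc,name,substrate_class
N06AX22,agomelatine,CYP2C19_ONLY
N06AA04,clomipramine,CYP2C19_ONLY
N06AB10,escitalopram,CYP2C19_ONLY
N06AG02,moclobemide,CYP2C19_ONLY
N06AB06,sertraline,CYP2C19_ONLY
N06AA01,desipramine,CYP2D6_ONLY
N06AX21,duloxetine,CYP2D6_ONLY
N06AB03,fluoxetine,CYP2D6_ONLY
N06AB08,fluvoxamine,CYP2D6_ONLY
N06AA21,maprotiline,CYP2D6_ONLY
N06AX03,mianserin,CYP2D6_ONLY
N06AX11,mirtazapine,CYP2D6_ONLY
N06AA10,nortriptyline,CYP2D6_ONLY
N06AB05,paroxetine,CYP2D6_ONLY
N06AX05,trazodone,CYP2D6_ONLY
N06AX16,venlafaxine,CYP2D6_ONLY
N06AX26,vortioxetine,CYP2D6_ONLY
N06AA09,amitriptyline,BOTH
N06AB04,citalopram,BOTH
N06AA12,doxepin,BOTH
N06AA02,imipramine,BOTH
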