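patch_name,r,g,b,is_neutral
dark_skin,0.45098039,0.32156863,0.26666667,0
light_skin,0.76078431,0.58823529,0.50980392,0
blue_sky,0.38431373,0.47843137,0.61568627,0
foliage,0.34117647,0.42352941,0.26274510,0
blue_flower,0.52156863,0.50196078,0.69411765,0
bluish_green,0.40392157,0.74117647,0.66666667,0
orange,0.83921569,0.49411765,0.17254902,0
purplish_blue,0.31372549,0.35686275,0.65098039,0
moderate_red,0.75686275,0.35294118,0.38823529,0
purple,0.36862745,0.23529412,0.42352941,0
yellow_green,0.61568627,0.73725490,0.25098039,0
orange_yellow,0.87843137,0.63921569,0.18039216,0
blue,0.21960784,0.23921569,0.58823529,0
green,0.27450980,0.58039216,0.28627451,0
red,0.68627451,0.21176471,0.23529412,0
yellow,0.90588235,0.78039216,0.12156863,0
magenta,0.73333333,0.33725490,0.58431373,0
cyan,0.03137255,0.52156863,0.63137255,0
white,0.95294118,0.95294118,0.94901961,1
neutral_8,0.78431373,0.78431373,0.78431373,1
neutral_6_5,0.62745098,0.62745098,0.62745098,1
neutral_5,0.47843137,0.47843137,0.47450980,1
neutral_3_5,0.33333333,0.33333333,0.33333333,1
black,0.20392157,0.20392157,0.20392157,1
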